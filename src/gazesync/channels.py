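"""Electrode montage constants for the dual 32-channel 10-20 layout."""

# Biosemi 32-channel 10-20 layout, cap order.
BIOSEMI32 = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

#: Parietal/occipital cluster used for event-locked ERP/ITC analyses.
OCCIPITAL_CLUSTER = ("PO3", "PO4", "O1", "Oz", "O2")

#: Vertex electrodes used for the non-event-locked inter-brain analyses.
CENTRAL = ("C3", "C4")

#: Frontal channels that carry saccade-like transients.
FRONTAL = ("Fp1", "Fp2", "AF3", "AF4")


def channel_indices(labels, subset):
    """Indices of ``subset`` labels within ``labels`` (order of ``subset``)."""
    lookup = {lab: i for i, lab in enumerate(labels)}
    missing = [lab for lab in subset if lab not in lookup]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    return [lookup[lab] for lab in subset]
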