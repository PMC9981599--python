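"""Config-driven orchestration of the three analysis families.

A cohort of dyads (simulated or loaded from disk) is preprocessed and fed
through:

* the non-event-locked inter-brain family: per-look gaze-state segments,
  1:n count matching, windowed PLV and bidirectional PDC over the central
  electrodes (C3, C4), Theta/Alpha band averages, dyad-surrogate nulls
  with z-score p-values (Bonferroni), 2x2 RM-ANOVA + Tukey-Kramer and
  JZS Bayes factors;
* the event-locked inter-brain family: time-frequency PLV/PDC maps around
  the four onset categories (sender role x gaze type), random-event
  surrogate baselines and mutual-vs-non-mutual contrasts via cluster
  permutation at alpha 0.025;
* the intra-brain family: occipital-cluster ERPs (baseline correction,
  adaptive-mean components, onset permutation tests) and ITC maps
  (cluster alpha 0.05) for sender/receiver x mutual/non-mutual onsets.

Participants contributing fewer than ``min_onsets`` (default 5) events in
a required condition are excluded from that family, with reasons logged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .channels import CENTRAL, OCCIPITAL_CLUSTER, channel_indices
from .connectivity import fit_var, pdc_from_var, select_var_order_bic
from .erp import baseline_correct, component_amplitudes, erp_onset_permutation_test
from .preprocess import (
    extract_event_epochs,
    match_condition_counts,
    preprocess_recording,
    segment_by_gaze_state,
)
from .simulate import DyadRecording, SimulationConfig, simulate_dyad
from .stats import (
    cluster_test_paired,
    cluster_test_vs_null,
    jzs_bayes_factor_paired,
    rm_anova_2x2,
    surrogate_dyad_null,
    valid_onset_samples,
    zscore_pvalue,
)
from .timefreq import ALPHA, THETA, band_average, default_cycles, default_freqs, morlet_decompose

__all__ = [
    "CohortRunConfig",
    "derive_dyad_seed",
    "simulate_cohort",
    "run_nonevent_analysis",
    "run_event_locked_analysis",
    "run_intrabrain_analysis",
    "run_cohort",
    "write_report",
]

GAZE_TYPES = ("mutual", "nonmutual")
SENDER_CATEGORIES = tuple(
    f"{role}_sender_{g}" for role in ("infant", "adult") for g in GAZE_TYPES
)


@dataclass
class CohortRunConfig:
    """Everything needed for one reproducible cohort run."""

    n_dyads: int = 55
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    families: Sequence[str] = ("nonevent", "event_interbrain", "event_intrabrain")
    central: Sequence[str] = CENTRAL
    occipital: Sequence[str] = OCCIPITAL_CLUSTER
    bands: dict = field(default_factory=lambda: {"Theta": THETA, "Alpha": ALPHA})
    epoch_window: tuple = (-2.5, 2.5)
    baseline_window: tuple = (-1.0, -0.7)
    n_perm: int = 1000
    alpha_interbrain: float = 0.025
    alpha_itc: float = 0.05
    forming_alpha: float = 0.05
    min_onsets: int = 5
    var_order: Optional[int] = 5  # None => estimate via per-segment BIC average
    max_order: int = 10
    window_s: float = 1.0
    pdc_step_s: float = 0.25
    map_step_s: float = 0.05
    phase_decim: int = 4
    bonferroni: Optional[int] = None  # default: number of metrics tested
    out_dir: Optional[str] = None

    def with_(self, **kw):
        return replace(self, **kw)


def derive_dyad_seed(base_seed: int, index: int) -> int:
    """Stable per-dyad sub-seed (< 2^31)."""
    return int(np.random.SeedSequence([int(base_seed), int(index)]).generate_state(1)[0] % 2**31)


def simulate_cohort(cfg: CohortRunConfig):
    """One DyadRecording per dyad, each with its own derived seed."""
    return [
        simulate_dyad(replace(cfg.sim, seed=derive_dyad_seed(cfg.seed, i)))
        for i in range(cfg.n_dyads)
    ]


def _unit_phasors(coefs: np.ndarray) -> np.ndarray:
    mag = np.abs(coefs)
    mag[mag == 0] = 1.0
    return (coefs / mag).astype(np.complex64)


def _nonevent_band_freqs(bands) -> np.ndarray:
    """Grid frequencies covering the configured bands (subset of 2..18 Hz)."""
    grid = default_freqs()
    lo = min(b[0] for b in bands.values())
    hi = max(b[1] for b in bands.values())
    return grid[(grid >= lo) & (grid <= hi)]


def _nonevent_cycles(freqs) -> np.ndarray:
    grid = default_freqs()
    cyc = default_cycles()
    return np.array([cyc[np.argmin(np.abs(grid - f))] for f in freqs])


# --------------------------------------------------------------------------
# non-event-locked family


def _nonevent_features(dyad, mask, cfg: CohortRunConfig):
    """Per-condition phase/broadband windows on the central electrodes.

    Returns None (with a reason) when either matched condition is shorter
    than one analysis window.
    """
    segs = segment_by_gaze_state(dyad, mask=mask)
    mut, non = match_condition_counts(segs["mutual"], segs["nonmutual"])
    w = int(round(cfg.window_s * dyad.fs))
    if min(mut.total_samples, non.total_samples) < w:
        return None, "insufficient_matched_data"
    idx = channel_indices(list(dyad.channel_labels), cfg.central)
    freqs = _nonevent_band_freqs(cfg.bands)
    cycles = _nonevent_cycles(freqs)
    out = {}
    for segset in (mut, non):
        feats = {"phasors": {}, "bb": {}}
        for role in ("infant", "adult"):
            seglist = getattr(segset, role)
            ph_wins, bb_wins = [], []
            for seg in seglist:
                x = seg[idx]  # (2, T)
                n_win = x.shape[1] // w
                if n_win == 0:
                    continue
                tf = morlet_decompose(x, dyad.fs, freqs, cycles)
                z = _unit_phasors(tf.coefficients)[..., : n_win * w]
                z = z.reshape(2, len(freqs), n_win, w).transpose(2, 0, 1, 3)
                ph_wins.append(z[..., :: cfg.phase_decim])
                bb = x[:, : n_win * w].reshape(2, n_win, w).transpose(1, 0, 2)
                bb_wins.append(bb.astype(np.float32))
            feats["phasors"][role] = (
                np.concatenate(ph_wins) if ph_wins else np.empty((0, 2, len(freqs), 0), complex)
            )
            feats["bb"][role] = np.concatenate(bb_wins) if bb_wins else np.empty((0, 2, w))
        if min(f.shape[0] for f in feats["phasors"].values()) == 0:
            return None, "no_full_window_in_condition"
        out[segset.state] = feats
    return out, None


def _pair_metrics(feat_i, feat_j, freqs, bands, order, fs):
    """12-vector of synchrony metrics for one (infant_i, adult_j) pairing.

    Order: for cond in (mutual, nonmutual), for metric in
    (PLV, PDC I->A, PDC A->I), for band in the configured band order.
    """
    vals = []
    for cond in GAZE_TYPES:
        zi = feat_i[cond]["phasors"]["infant"]
        za = feat_j[cond]["phasors"]["adult"]
        n = min(zi.shape[0], za.shape[0])
        plv_f = np.abs((zi[:n] * np.conj(za[:n])).mean(axis=-1)).mean(axis=(0, 1))
        bi = feat_i[cond]["bb"]["infant"]
        ba = feat_j[cond]["bb"]["adult"]
        nb = min(bi.shape[0], ba.shape[0])
        ia, ai = [], []
        for k in range(nb):
            for e in range(bi.shape[1]):
                seg = np.column_stack([bi[k, e], ba[k, e]]).astype(float)
                try:
                    m = fit_var(seg, order=order, fs=fs)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                p = pdc_from_var(m, freqs)
                ia.append(p[1, 0])
                ai.append(p[0, 1])
        pdc_ia = np.mean(ia, axis=0) if ia else np.full(len(freqs), np.nan)
        pdc_ai = np.mean(ai, axis=0) if ai else np.full(len(freqs), np.nan)
        for metric_f in (plv_f, pdc_ia, pdc_ai):
            for band in bands.values():
                vals.append(band_average(metric_f, freqs, band))
    return np.array(vals)


def nonevent_metric_names(bands) -> list:
    return [
        f"{cond}_{metric}_{band}"
        for cond in GAZE_TYPES
        for metric in ("PLV", "PDC_IA", "PDC_AI")
        for band in bands
    ]


def estimate_cohort_var_order(features, max_order: int = 10) -> int:
    """Average of per-segment BIC-selected orders across dyads, rounded."""
    orders = []
    for feat in features:
        for cond in GAZE_TYPES:
            bi = feat[cond]["bb"]["infant"]
            ba = feat[cond]["bb"]["adult"]
            for k in range(min(bi.shape[0], ba.shape[0])):
                seg = np.column_stack([bi[k, 0], ba[k, 0]]).astype(float)
                try:
                    orders.append(select_var_order_bic(seg, max_order=max_order))
                except (ValueError, np.linalg.LinAlgError):
                    continue
    if not orders:
        raise ValueError("no segment usable for order estimation")
    return int(round(float(np.mean(orders))))


def run_nonevent_analysis(dyads, cfg: CohortRunConfig, preprocessed=None):
    """Non-event-locked inter-brain synchrony analysis over a cohort."""
    rng = np.random.default_rng(derive_dyad_seed(cfg.seed, 10_001))
    freqs = _nonevent_band_freqs(cfg.bands)
    features, excluded = [], {}
    for i, dyad in enumerate(dyads):
        clean, mask, _ = preprocessed[i] if preprocessed else preprocess_recording(dyad)
        feat, reason = _nonevent_features(clean, mask, cfg)
        if feat is None:
            excluded[i] = reason
        else:
            features.append(feat)
    if len(features) < 2:
        raise ValueError(f"fewer than 2 dyads usable; exclusions: {excluded}")
    order = cfg.var_order or estimate_cohort_var_order(features, cfg.max_order)

    def metric_fn(feat_i, feat_j):
        return _pair_metrics(feat_i, feat_j, freqs, cfg.bands, order, cfg.sim.fs)

    null = surrogate_dyad_null(features, features, metric_fn, n_perm=cfg.n_perm, rng=rng)
    names = nonevent_metric_names(cfg.bands)
    k = cfg.bonferroni or len(names)
    pvals, zvals = zscore_pvalue(null.observed, null.null, bonferroni=k)

    per_dyad = np.stack([metric_fn(f, f) for f in features])  # cached
    band_names = list(cfg.bands)
    anova, bayes = {}, {}
    for m, metric in enumerate(("PLV", "PDC_IA", "PDC_AI")):
        # (n, gaze, band) cell table
        cells = np.empty((per_dyad.shape[0], 2, 2))
        for c, cond in enumerate(GAZE_TYPES):
            for b in range(2):
                cells[:, c, b] = per_dyad[:, names.index(f"{cond}_{metric}_{band_names[b]}")]
        anova[metric] = rm_anova_2x2(cells, factor_a="gaze_type", factor_b="frequency")
        for b, band in enumerate(band_names):
            bayes[f"{metric}_{band}"] = jzs_bayes_factor_paired(cells[:, 0, b], cells[:, 1, b])
    return {
        "metric_names": names,
        "observed": null.observed,
        "null": null,
        "p": pvals,
        "z": zvals,
        "bonferroni": k,
        "per_dyad": pd.DataFrame(per_dyad, columns=names),
        "anova": anova,
        "bayes": bayes,
        "order_used": order,
        "excluded": excluded,
        "n_included": len(features),
    }


# --------------------------------------------------------------------------
# event-locked machinery shared by the inter- and intra-brain families


def _matched_category_events(events, min_onsets):
    """Count-matched event lists per sender category; None if below minimum."""
    out = {}
    for role in ("infant", "adult"):
        per_type = {
            g: [e for e in events if e.sender == role and e.gaze_type == g] for g in GAZE_TYPES
        }
        n = min(len(v) for v in per_type.values())
        for g in GAZE_TYPES:
            key = f"{role}_sender_{g}"
            out[key] = per_type[g][:n] if n >= min_onsets else None
    return out


class _DyadEventContext:
    """Continuous phasors + broadband cluster means for one cleaned dyad."""

    def __init__(self, dyad, mask, cfg: CohortRunConfig, rng):
        self.fs = dyad.fs
        self.cfg = cfg
        self.rng = rng
        self.n_samples = dyad.n_samples
        occ = channel_indices(list(dyad.channel_labels), cfg.occipital)
        self.bb = {
            "infant": dyad.infant[occ].mean(axis=0),
            "adult": dyad.adult[occ].mean(axis=0),
        }
        self.freqs = default_freqs()
        self.phasors = {
            role: _unit_phasors(morlet_decompose(self.bb[role], dyad.fs, self.freqs).coefficients)
            for role in ("infant", "adult")
        }
        step = max(1, int(round(cfg.map_step_s * dyad.fs)))
        w0, w1 = cfg.epoch_window
        self.offsets = np.arange(int(round(w0 * dyad.fs)), int(round(w1 * dyad.fs)) + 1, step)
        self.map_times = self.offsets / dyad.fs
        self.candidates = valid_onset_samples(dyad.n_samples, dyad.fs, cfg.epoch_window, mask)
        self.mask = mask
        cand = set(self.candidates.tolist())
        self.events = [
            e for e in dyad.events if int(round(e.onset_time * dyad.fs)) in cand
        ]
        self.categories = _matched_category_events(self.events, cfg.min_onsets)

    def onset_samples(self, events):
        return np.array([int(round(e.onset_time * self.fs)) for e in events], dtype=int)

    def _gather(self, phasors, onsets):
        idx = onsets[:, None] + self.offsets[None, :]
        return phasors[:, idx]  # (F, K, nT)

    def itc_map(self, role, onsets):
        return np.abs(self._gather(self.phasors[role], onsets).mean(axis=1))

    def plv_map(self, onsets):
        zi = self._gather(self.phasors["infant"], onsets)
        za = self._gather(self.phasors["adult"], onsets)
        return np.abs((zi * np.conj(za)).mean(axis=1))

    def surrogate_onsets(self, k, n_perm):
        replace = len(self.candidates) < 4 * k
        return self.rng.choice(self.candidates, size=(n_perm, k), replace=replace)

    def surrogate_itc_maps(self, role, k, n_perm):
        on = self.surrogate_onsets(k, n_perm)  # (n_perm, k)
        z = self._gather(self.phasors[role], on.ravel())  # (F, n_perm*k, nT)
        z = z.reshape(len(self.freqs), n_perm, k, -1)
        return np.abs(z.mean(axis=2)).transpose(1, 0, 2)  # (n_perm, F, nT)

    def surrogate_plv_maps(self, k, n_perm):
        on = self.surrogate_onsets(k, n_perm).ravel()
        zi = self._gather(self.phasors["infant"], on)
        za = self._gather(self.phasors["adult"], on)
        z = (zi * np.conj(za)).reshape(len(self.freqs), n_perm, k, -1)
        return np.abs(z.mean(axis=2)).transpose(1, 0, 2)

    # -- fast event-locked PDC -------------------------------------------
    # Windows are interior slices of epochs cut from the continuous
    # recording, so the p samples preceding a window are legitimate
    # within-trial history; VAR normal equations for any pooled window
    # set are differences of cumulative Gram matrices, which makes the
    # per-permutation refits cheap.

    def _pdc_cache(self):
        if hasattr(self, "_grams"):
            return self._grams
        p = self.cfg.var_order or 5
        z = np.column_stack([self.bb["infant"], self.bb["adult"]])  # (T, 2)
        T = z.shape[0]
        L = np.zeros((T, 2 * p))
        for k in range(1, p + 1):
            L[k:, 2 * (k - 1) : 2 * k] = z[:-k]
        outer_LL = np.einsum("ti,tj->tij", L, L)
        outer_Lz = np.einsum("ti,tj->tij", L, z)
        outer_zz = np.einsum("ti,tj->tij", z, z)
        G = np.concatenate([np.zeros((1, 2 * p, 2 * p)), np.cumsum(outer_LL, axis=0)])
        C = np.concatenate([np.zeros((1, 2 * p, 2)), np.cumsum(outer_Lz, axis=0)])
        S = np.concatenate([np.zeros((1, 2, 2)), np.cumsum(outer_zz, axis=0)])
        self._grams = (p, G, C, S)
        return self._grams

    def _pdc_window_grid(self):
        w = int(round(self.cfg.window_s * self.fs))
        step = max(1, int(round(self.cfg.pdc_step_s * self.fs)))
        w0, w1 = self.cfg.epoch_window
        length = int(round((w1 - w0) * self.fs))
        starts = np.arange(0, length - w + 1, step)
        centres = w0 + (starts + w / 2) / self.fs
        pre = int(round(-w0 * self.fs))
        return w, starts - pre, centres  # starts relative to the onset sample

    def _pdc_maps_batch(self, onsets_batch: np.ndarray):
        """PDC maps for a batch of onset sets: (n_batch, F, n_centres) x 2."""
        p, G, C, S = self._pdc_cache()
        w, rel_starts, centres = self._pdc_window_grid()
        n_batch, K = onsets_batch.shape
        F = len(self.freqs)
        out_ia = np.empty((n_batch, F, len(rel_starts)))
        out_ai = np.empty((n_batch, F, len(rel_starts)))
        k_idx = np.arange(1, p + 1)
        phase = np.exp(-2j * np.pi * np.outer(self.freqs, k_idx) / self.fs)  # (F, p)
        eye = np.eye(2 * p) * 1e-9
        for wi, rs in enumerate(rel_starts):
            a = onsets_batch + rs
            b = a + w
            gram = G[b].sum(axis=1) - G[a].sum(axis=1)  # (n_batch, 2p, 2p)
            cross = C[b].sum(axis=1) - C[a].sum(axis=1)  # (n_batch, 2p, 2)
            B = np.linalg.solve(gram + eye, cross)  # (n_batch, 2p, 2)
            # coefs[n, k] = B[n, 2k:2k+2, :].T
            coefs = B.reshape(n_batch, p, 2, 2).transpose(0, 1, 3, 2)
            Abar = np.eye(2)[None, None] - np.einsum("fk,nkij->nfij", phase, coefs.astype(complex))
            mag2 = np.abs(Abar) ** 2
            col0 = np.sqrt(mag2[..., 0, 0] + mag2[..., 1, 0])
            col1 = np.sqrt(mag2[..., 0, 1] + mag2[..., 1, 1])
            out_ia[:, :, wi] = np.abs(Abar[..., 1, 0]) / np.where(col0 == 0, 1, col0)
            out_ai[:, :, wi] = np.abs(Abar[..., 0, 1]) / np.where(col1 == 0, 1, col1)
        return out_ia, out_ai, centres

    def epochs(self, role, onsets):
        """Broadband cluster-mean trials (K, n_samples_epoch)."""
        w0, w1 = self.cfg.epoch_window
        pre = int(round(-w0 * self.fs))
        length = int(round((w1 - w0) * self.fs))
        return np.stack([self.bb[role][s - pre : s - pre + length] for s in onsets])

    def pdc_maps(self, onsets):
        ia, ai, centres = self._pdc_maps_batch(np.asarray(onsets)[None, :])
        from .connectivity import SynchronyMap

        k = len(onsets)
        return (
            SynchronyMap("PDC_I->A", ia[0], self.freqs, times=centres, n_trials=k),
            SynchronyMap("PDC_A->I", ai[0], self.freqs, times=centres, n_trials=k),
        )

    def surrogate_pdc_maps(self, k, n_perm):
        on = self.surrogate_onsets(k, n_perm)
        ia, ai, _ = self._pdc_maps_batch(on)
        return ia, ai


def _prepare_contexts(dyads, cfg, preprocessed, seed_offset):
    contexts, excluded = [], {}
    for i, dyad in enumerate(dyads):
        clean, mask, _ = preprocessed[i] if preprocessed else preprocess_recording(dyad)
        rng = np.random.default_rng(derive_dyad_seed(cfg.seed, seed_offset + i))
        ctx = _DyadEventContext(clean, mask, cfg, rng)
        if all(v is None for v in ctx.categories.values()):
            excluded[i] = "too_few_onsets"
            continue
        contexts.append(ctx)
    return contexts, excluded


def _group_cluster_vs_null(obs_maps, null_maps, forming_alpha, alpha):
    """Group-mean observed map against group-mean permutation maps."""
    group_obs = np.mean(obs_maps, axis=0)
    group_null = np.mean(null_maps, axis=0)  # (n_perm, F, T)
    return group_obs, cluster_test_vs_null(group_obs, group_null, forming_alpha, alpha)


def run_event_locked_analysis(dyads, cfg: CohortRunConfig, preprocessed=None):
    """Event-locked inter-brain PLV/PDC around the four onset categories."""
    n_perm = max(cfg.n_perm, 200)
    contexts, excluded = _prepare_contexts(dyads, cfg, preprocessed, 20_000)
    if not contexts:
        raise ValueError("no dyad with enough onsets")
    results = {"excluded": excluded, "categories": {}, "contrasts": {}}
    per_dyad_maps = {cat: {"plv": [], "pdc_ia": [], "pdc_ai": []} for cat in SENDER_CATEGORIES}
    null_maps = {cat: {"plv": [], "pdc_ia": [], "pdc_ai": []} for cat in SENDER_CATEGORIES}
    for ctx in contexts:
        for cat in SENDER_CATEGORIES:
            evs = ctx.categories[cat]
            if evs is None or len(evs) < 2:
                continue
            onsets = ctx.onset_samples(evs)
            per_dyad_maps[cat]["plv"].append(ctx.plv_map(onsets))
            null_maps[cat]["plv"].append(ctx.surrogate_plv_maps(len(evs), n_perm))
            m_ia, m_ai = ctx.pdc_maps(onsets)
            per_dyad_maps[cat]["pdc_ia"].append(m_ia.values)
            per_dyad_maps[cat]["pdc_ai"].append(m_ai.values)
            s_ia, s_ai = ctx.surrogate_pdc_maps(len(evs), n_perm)
            null_maps[cat]["pdc_ia"].append(s_ia)
            null_maps[cat]["pdc_ai"].append(s_ai)
        if hasattr(ctx, "_grams"):
            del ctx._grams  # ~100 MB of cumulative Gram matrices per dyad
    ctx0 = contexts[0]
    results["freqs"] = ctx0.freqs
    results["map_times"] = ctx0.map_times
    for cat in SENDER_CATEGORIES:
        results["categories"][cat] = {}
        for metric in ("plv", "pdc_ia", "pdc_ai"):
            maps = per_dyad_maps[cat][metric]
            if len(maps) < 2:
                continue
            group_obs, cres = _group_cluster_vs_null(
                maps, null_maps[cat][metric], cfg.forming_alpha, cfg.alpha_interbrain
            )
            results["categories"][cat][metric] = {
                "group_map": group_obs,
                "cluster": cres,
                "n_dyads": len(maps),
            }
    # mutual vs non-mutual contrasts per sender role and metric
    rng = np.random.default_rng(derive_dyad_seed(cfg.seed, 20_999))
    for role in ("infant", "adult"):
        for metric in ("plv", "pdc_ia", "pdc_ai"):
            a = per_dyad_maps[f"{role}_sender_mutual"][metric]
            b = per_dyad_maps[f"{role}_sender_nonmutual"][metric]
            n = min(len(a), len(b))
            if n < 3:
                continue
            results["contrasts"][f"{role}_sender_{metric}"] = cluster_test_paired(
                np.stack(a[:n]),
                np.stack(b[:n]),
                forming_alpha=cfg.forming_alpha,
                alpha=cfg.alpha_interbrain,
                n_perm=n_perm,
                rng=rng,
            )
    results["n_included"] = len(contexts)
    return results


def run_intrabrain_analysis(dyads, cfg: CohortRunConfig, preprocessed=None):
    """ERP and ITC analysis per population (infant/adult) and event role."""
    n_perm = max(cfg.n_perm, 200)
    contexts, excluded = _prepare_contexts(dyads, cfg, preprocessed, 30_000)
    if not contexts:
        raise ValueError("no dyad with enough onsets")
    ctx0 = contexts[0]
    w0, w1 = cfg.epoch_window
    length = int(round((w1 - w0) * ctx0.fs))
    erp_times = w0 + np.arange(length) / ctx0.fs
    results = {
        "excluded": excluded,
        "freqs": ctx0.freqs,
        "map_times": ctx0.map_times,
        "erp_times": erp_times,
        "populations": {},
        "contrasts": {},
        "n_included": len(contexts),
    }
    # population = the subject whose brain is analysed; role = its part in
    # the gaze shift.  The subject is "sender" for its own shifts and
    # "receiver" for its partner's shifts; both lock to the sender's shift.
    cases = {}
    for pop in ("infant", "adult"):
        partner = "adult" if pop == "infant" else "infant"
        for role, sender in (("sender", pop), ("receiver", partner)):
            for g in GAZE_TYPES:
                cases[(pop, role, g)] = f"{sender}_sender_{g}"
    store = {key: {"erp": [], "itc": [], "itc_null": []} for key in cases}
    rng = np.random.default_rng(derive_dyad_seed(cfg.seed, 30_999))
    for ctx in contexts:
        for (pop, role, g), cat in cases.items():
            evs = ctx.categories[cat]
            if evs is None or len(evs) < 2:
                continue
            onsets = ctx.onset_samples(evs)
            epochs = ctx.epochs(pop, onsets)
            epochs = baseline_correct(epochs, erp_times, cfg.baseline_window)
            store[(pop, role, g)]["erp"].append(epochs.mean(axis=0))
            store[(pop, role, g)]["itc"].append(ctx.itc_map(pop, onsets))
            store[(pop, role, g)]["itc_null"].append(
                ctx.surrogate_itc_maps(pop, len(evs), n_perm)
            )
    for (pop, role, g), d in store.items():
        if len(d["erp"]) < 3:
            continue
        erps = np.stack(d["erp"])
        test = erp_onset_permutation_test(
            erps, erp_times, window=(0.0, 0.5), n_perm=n_perm, rng=rng
        )
        grand = erps.mean(axis=0)
        comps = component_amplitudes(grand, erp_times, pop)
        subject_comps = [component_amplitudes(e, erp_times, pop) for e in erps]
        group_obs, cres = _group_cluster_vs_null(
            d["itc"], d["itc_null"], cfg.forming_alpha, cfg.alpha_itc
        )
        results["populations"][(pop, role, g)] = {
            "erp_test": test,
            "grand_erp": grand,
            "components": comps,
            "subject_components": subject_comps,
            "itc_group_map": group_obs,
            "itc_cluster": cres,
            "n_subjects": len(d["erp"]),
        }
    # mutual vs non-mutual ITC contrasts and sender component contrasts
    for pop in ("infant", "adult"):
        for role in ("sender", "receiver"):
            a = store[(pop, role, "mutual")]["itc"]
            b = store[(pop, role, "nonmutual")]["itc"]
            n = min(len(a), len(b))
            if n >= 3:
                results["contrasts"][f"{pop}_{role}_itc"] = cluster_test_paired(
                    np.stack(a[:n]),
                    np.stack(b[:n]),
                    forming_alpha=cfg.forming_alpha,
                    alpha=cfg.alpha_itc,
                    n_perm=n_perm,
                    rng=rng,
                )
    return results


def run_cohort(cfg: CohortRunConfig, dyads=None):
    """Simulate (if needed), preprocess once, and run the selected families."""
    if dyads is None:
        dyads = simulate_cohort(cfg)
    preprocessed = [preprocess_recording(d) for d in dyads]
    report = {"config": cfg, "n_dyads": len(dyads)}
    if "nonevent" in cfg.families:
        report["nonevent"] = run_nonevent_analysis(dyads, cfg, preprocessed)
    if "event_interbrain" in cfg.families:
        report["event_interbrain"] = run_event_locked_analysis(dyads, cfg, preprocessed)
    if "event_intrabrain" in cfg.families:
        report["event_intrabrain"] = run_intrabrain_analysis(dyads, cfg, preprocessed)
    if cfg.out_dir:
        write_report(report, cfg.out_dir)
    return report


# --------------------------------------------------------------------------
# report serialization


def _cluster_rows(label, cres):
    return [
        {
            "test": label,
            "cluster": i,
            "mass": c["mass"],
            "size": len(c["indices"]),
            "sign": c.get("sign", 1),
            "p_corrected": c["p"],
        }
        for i, c in enumerate(cres.clusters)
    ]


def write_report(report, out_dir):
    """Machine-readable CSV/JSON summary of a cohort run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"n_dyads": report["n_dyads"], "seed": report["config"].seed}
    if "nonevent" in report:
        ne = report["nonevent"]
        ne["per_dyad"].to_csv(out / "nonevent_per_dyad.csv", index_label="dyad")
        rows = []
        for name, obs, p, z in zip(ne["metric_names"], ne["observed"], ne["p"], ne["z"]):
            rows.append({"test": name, "observed": obs, "z": z, "p_corrected": p})
        pd.DataFrame(rows).to_csv(out / "nonevent_surrogate_tests.csv", index=False)
        stat_rows = []
        for metric, eff in ne["anova"].items():
            for key, v in eff.items():
                if key == "pairwise":
                    continue
                stat_rows.append(
                    {"metric": metric, "effect": key, "F": v["F"], "df1": v["df"][0],
                     "df2": v["df"][1], "p": v["p"]}
                )
        pd.DataFrame(stat_rows).to_csv(out / "nonevent_anova.csv", index=False)
        bf_rows = [
            {"test": k, "BF10": v["BF10"], "BF01": v["BF01"], "t": v["t"], "n": v["n"]}
            for k, v in ne["bayes"].items()
        ]
        pd.DataFrame(bf_rows).to_csv(out / "nonevent_bayes_factors.csv", index=False)
        manifest["nonevent"] = {
            "order_used": ne["order_used"],
            "n_included": ne["n_included"],
            "excluded": {str(k): v for k, v in ne["excluded"].items()},
        }
    if "event_interbrain" in report:
        ev = report["event_interbrain"]
        rows = []
        for cat, metrics in ev["categories"].items():
            for metric, r in metrics.items():
                rows += _cluster_rows(f"{cat}_{metric}_vs_surrogate", r["cluster"])
        for label, cres in ev["contrasts"].items():
            rows += _cluster_rows(f"{label}_mutual_vs_nonmutual", cres)
        pd.DataFrame(rows).to_csv(out / "event_interbrain_clusters.csv", index=False)
        manifest["event_interbrain"] = {
            "n_included": ev["n_included"],
            "excluded": {str(k): v for k, v in ev["excluded"].items()},
        }
    if "event_intrabrain" in report:
        ib = report["event_intrabrain"]
        rows, erp_rows = [], []
        for (pop, role, g), r in ib["populations"].items():
            label = f"{pop}_{role}_{g}"
            rows += _cluster_rows(f"{label}_itc_vs_surrogate", r["itc_cluster"])
            erp_rows.append(
                {"case": label, "p_max": r["erp_test"]["p_max"],
                 "p_min": r["erp_test"]["p_min"], "n_subjects": r["n_subjects"]}
            )
        for label, cres in ib["contrasts"].items():
            rows += _cluster_rows(f"{label}_mutual_vs_nonmutual", cres)
        pd.DataFrame(rows).to_csv(out / "intrabrain_clusters.csv", index=False)
        pd.DataFrame(erp_rows).to_csv(out / "intrabrain_erp_tests.csv", index=False)
        manifest["event_intrabrain"] = {
            "n_included": ib["n_included"],
            "excluded": {str(k): v for k, v in ib["excluded"].items()},
        }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
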