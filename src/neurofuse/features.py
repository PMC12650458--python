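"""End-to-end feature extraction: clips -> windowed multimodal GC bundles.

Per clip: EEG is band-pass filtered (4-45 Hz) and split into the four
rhythm bands; fNIRS hemoglobin series are band-pass filtered to the
task-related 0.01-0.2 Hz range and upsampled to the common 200 Hz rate;
all streams are cut into 3 s windows with a 1.5 s hop. Per window, the
within-EEG GC matrix of each band and the fNIRS->EEG cross-modal GC
matrix per band (HbO2 by default) are estimated; the raw HbO2+HbR
window forms the time-series stream.

A single AR order per (band, direction) is selected once per run by BIC
on a subsample of channel pairs and then shared across all windows, so
matrix entries stay comparable.
"""

from __future__ import annotations

import numpy as np

from .granger import cross_modal_gc, eeg_gc_matrix, select_order
from .model import FeatureBundle
from .preprocess import (
    BAND_NAMES,
    COMMON_FS,
    Recording,
    bandpass,
    extract_bands,
    resample,
    segment,
)
from .synthetic import Dataset

__all__ = ["preprocess_clip", "extract_features", "dataset_to_bundles"]


def preprocess_clip(eeg: Recording, hbo2: Recording, hbr: Recording):
    """Filter, band-split and rate-align one clip's three recordings."""
    if eeg.fs != COMMON_FS:
        eeg = resample(eeg, COMMON_FS)
    eeg = bandpass(eeg, 4.0, 45.0)
    bands = extract_bands(eeg)
    aligned = []
    for rec in (hbo2, hbr):
        rec = bandpass(rec, 0.01, 0.2)
        aligned.append(resample(rec, COMMON_FS))
    # rate conversion can differ by one sample from the EEG stream
    n = min(eeg.n_samples, *(r.n_samples for r in aligned))
    bands = {k: r.copy_with(r.data[:, :n]) for k, r in bands.items()}
    hbo2_al = aligned[0].copy_with(aligned[0].data[:, :n])
    hbr_al = aligned[1].copy_with(aligned[1].data[:, :n])
    return bands, hbo2_al, hbr_al


def _choose_orders(
    windows,
    order_policy,
    max_order: int,
    seed: int,
) -> tuple[dict[str, int], dict[str, int]]:
    """Shared AR order per (band, direction), from a window subsample.

    Orders are BIC-selected on up to 20 random channel pairs drawn from
    the first few windows (fixed-integer policies skip the search).
    """
    if isinstance(order_policy, (int, np.integer)):
        k = int(order_policy)
        return {b: k for b in BAND_NAMES}, {b: k for b in BAND_NAMES}
    rng = np.random.default_rng(seed)
    eeg_orders: dict[str, int] = {}
    x_orders: dict[str, int] = {}
    probe = windows[: min(3, len(windows))]
    for band in BAND_NAMES:
        pairs = []
        for w in probe:
            e = w.eeg_bands[band]
            f = w.hbo2
            ne, nf = e.shape[0], f.shape[0]
            for _ in range(7):
                i, j = rng.choice(ne, size=2, replace=False)
                pairs.append(("eeg", e[j], e[i]))
                pairs.append(("x", e[rng.integers(ne)], f[rng.integers(nf)]))
        sel_e = [
            select_order(x, y, max_order, order_policy)
            for kind, x, y in pairs
            if kind == "eeg"
        ]
        sel_x = [
            select_order(x, y, max_order, order_policy)
            for kind, x, y in pairs
            if kind == "x"
        ]
        eeg_orders[band] = max(1, int(round(float(np.mean(sel_e)))))
        x_orders[band] = max(1, int(round(float(np.mean(sel_x)))))
    return eeg_orders, x_orders


def extract_features(
    windows,
    order_policy="bic",
    max_order: int = 5,
    chromophore: str = "hbo2",
    seed: int = 0,
) -> list[FeatureBundle]:
    """Turn windowed segments into per-window feature bundles.

    The cross-modal stream fed to the classifier is the fNIRS->EEG
    direction on the configured chromophore (HbO2 by default).
    """
    if not windows:
        return []
    eeg_orders, x_orders = _choose_orders(windows, order_policy, max_order, seed)
    bundles: list[FeatureBundle] = []
    for w in windows:
        band_recs = {
            b: Recording(w.eeg_bands[b], COMMON_FS, modality="eeg")
            for b in BAND_NAMES
        }
        fnirs_data = w.hbo2 if chromophore == "hbo2" else w.hbr
        fnirs_rec = Recording(fnirs_data, COMMON_FS, modality=chromophore)
        eeg_gc = []
        xmodal = []
        for b in BAND_NAMES:
            mat = eeg_gc_matrix({b: band_recs[b]}, order_policy=eeg_orders[b])[b]
            eeg_gc.append(mat.values)
            f2e, _ = cross_modal_gc(
                band_recs[b],
                fnirs_rec,
                order_policy=x_orders[b],
                band=b,
                chromophore=chromophore,
                directions=("fnirs->eeg",),
            )
            xmodal.append(f2e.values)
        bundles.append(
            FeatureBundle(
                eeg_gc=np.stack(eeg_gc),
                fnirs_ts=np.vstack([w.hbo2, w.hbr]),
                xmodal_gc=np.stack(xmodal),
                label=w.label,
                clip_id=w.clip_id,
                subject_id=w.subject_id,
            )
        )
    return bundles


def dataset_to_bundles(
    dataset: Dataset,
    order_policy="bic",
    max_order: int = 5,
    chromophore: str = "hbo2",
    seed: int = 0,
) -> list[FeatureBundle]:
    """Full pipeline from a simulated dataset to feature bundles."""
    windows = []
    for clip in dataset.clips:
        bands, hbo2, hbr = preprocess_clip(clip.eeg, clip.hbo2, clip.hbr)
        windows.extend(
            segment(
                bands,
                hbo2,
                hbr,
                label=clip.label,
                clip_id=clip.clip_id,
                subject_id=clip.subject_id,
            )
        )
    return extract_features(
        windows,
        order_policy=order_policy,
        max_order=max_order,
        chromophore=chromophore,
        seed=seed,
    )
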