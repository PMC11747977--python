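"""Margin-inclusive standardization, PCA to eight components, infomax ICA.

Each preprocessed seizure segment is standardized per channel over the full
window (margins included, so the relative ictal amplitude rise is
preserved), reduced with PCA to the top eight principal components, and
unmixed with extended-infomax ICA.  The product of the two linear maps
gives per-component electrode weights whose normalized form is the scalp
topography used for visual and automated labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from mne.preprocessing import infomax

from .io_preprocess import Segment

DEFAULT_N_PC = 8


@dataclass
class PcaModel:
    loadings: np.ndarray  # n_pc x channels, orthonormal rows
    explained_variance: np.ndarray  # per-PC fraction of total variance
    n_pc: int


@dataclass
class IcaModel:
    unmixing: np.ndarray  # n_ic x n_pc
    seed: int
    converged: bool
    n_iter: int


@dataclass
class ComponentSet:
    """ICA decomposition of one segment: traces, weights and topographies.

    IC trace amplitudes are procedure-defined units (PDU): the PCA/ICA
    scaling is arbitrary, only the waveform shape is meaningful.
    """

    ic_traces: np.ndarray  # n_ic x samples
    electrode_weights: np.ndarray  # n_ic x channels
    topographies: np.ndarray  # weights row-normalized to max |.| = 1
    fs: float
    core_interval: tuple[float, float]
    t0_s: float = 0.0
    channel_names: list[str] = field(default_factory=list)
    pca: PcaModel | None = None
    ica: IcaModel | None = None
    brain_scores: np.ndarray | None = None


def standardize_with_margins(segment: Segment) -> tuple[Segment, np.ndarray, np.ndarray]:
    """Zero-mean, unit-variance scale each channel over the full segment.

    The statistics are computed over margins *and* core, so a channel whose
    amplitude rises during the seizure keeps that rise relative to its own
    baseline.  Returns (standardized segment, means, scales); a
    zero-variance channel gets scale 1 and a warning flag in provenance.
    """
    data = segment.data
    mean = data.mean(axis=1)
    std = data.std(axis=1)
    degenerate = std <= 0
    scale = np.where(degenerate, 1.0, std)
    out = (data - mean[:, None]) / scale[:, None]
    prov = dict(segment.provenance)
    prov["standardized"] = True
    if degenerate.any():
        prov["zero_variance_channels"] = [
            segment.channel_names[i] if segment.channel_names else i
            for i in np.flatnonzero(degenerate)
        ]
    return replace(segment, data=out, provenance=prov), mean, scale


def fit_pca(data: np.ndarray, n_pc: int) -> PcaModel:
    """Exact eigendecomposition of the channel covariance (channels are few)."""
    n_ch = data.shape[0]
    if n_ch < n_pc:
        raise ValueError(f"{n_ch} channels < n_pc={n_pc}")
    cov = np.cov(data)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|.| element of each eigenvector positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] *= -1
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PcaModel(loadings=evecs[:, :n_pc].T.copy(), explained_variance=frac[:n_pc], n_pc=n_pc)


def decompose(
    standardized: Segment, n_pc: int = DEFAULT_N_PC, seed: int = 0
) -> tuple[PcaModel, IcaModel, ComponentSet]:
    """PCA to ``n_pc`` components, extended-infomax ICA on the PC traces.

    IC ordering is by descending back-projected scalp variance; each IC's
    sign is fixed so its largest-|weight| electrode is positive.  A
    non-converged ICA is returned flagged (``IcaModel.converged``), never
    silently.
    """
    data = standardized.data
    n_ch, n_samp = data.shape
    if n_samp < 10 * n_ch:
        raise ValueError(f"{n_samp} samples < 10x{n_ch} channels; segment too short")
    pca = fit_pca(data, n_pc)
    pcs = pca.loadings @ data  # n_pc x samples
    max_iter = 512
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        unmix, n_iter = infomax(
            pcs.T,
            extended=True,
            max_iter=max_iter,
            w_change=1e-7,
            rng=seed,
            return_n_iter=True,
            verbose="error",
        )
    # Extended infomax updates in randomly permuted blocks, so the
    # per-iteration weight change rarely crosses a tight tolerance even
    # after the solution has settled; the tolerance acts as an early exit.
    # Convergence is therefore flagged on the trained result being finite
    # and well-conditioned (a diverged run blows up or degenerates).
    converged = bool(
        np.isfinite(unmix).all() and np.linalg.cond(unmix) < 1e6
    )
    ica = IcaModel(unmixing=unmix, seed=seed, converged=converged, n_iter=int(n_iter))
    weights = unmix @ pca.loadings  # n_ic x channels
    traces = unmix @ pcs
    # order by back-projected scalp variance: mixing column norm^2 * trace var
    mixing = np.linalg.pinv(weights)  # channels x n_ic
    bp_var = (mixing**2).sum(axis=0) * traces.var(axis=1)
    order = np.argsort(bp_var)[::-1]
    traces, weights = traces[order], weights[order]
    ica.unmixing = unmix[order]
    # sign convention: electrode with max |weight| made positive
    for i in range(weights.shape[0]):
        k = np.argmax(np.abs(weights[i]))
        if weights[i, k] < 0:
            weights[i] *= -1
            traces[i] *= -1
            ica.unmixing[i] *= -1
    topo = weights / np.max(np.abs(weights), axis=1, keepdims=True)
    comp = ComponentSet(
        ic_traces=traces,
        electrode_weights=weights,
        topographies=topo,
        fs=standardized.fs,
        core_interval=standardized.core_interval,
        t0_s=standardized.t0_s,
        channel_names=list(standardized.channel_names),
        pca=pca,
        ica=ica,
    )
    return pca, ica, comp


def electrode_weights(pca: PcaModel, ica: IcaModel) -> tuple[np.ndarray, np.ndarray]:
    """Combined unmixing x loadings map and its row-normalized topographies."""
    if ica.unmixing.shape[1] != pca.loadings.shape[0]:
        raise ValueError(
            f"ICA unmixing expects {ica.unmixing.shape[1]} PCs, "
            f"PCA provides {pca.loadings.shape[0]}"
        )
    weights = ica.unmixing @ pca.loadings
    topo = weights / np.max(np.abs(weights), axis=1, keepdims=True)
    return weights, topo
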