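"""Narrow-band coherence and functional-connectivity analysis.

Pipeline: per-parcel mean voltages with additive white Gaussian noise at a
target SNR -> second-order resonator filterbank -> analytic signals (Hilbert
transform) -> cross-spectral matrices -> magnitude-squared coherence (MSC)
per band -> exponential coherence-vs-distance fits (length constant lambda,
maximum coherence alpha, over the 0-100 mm domain) and functional
connectivity (percent of parcel pairs above a coherence threshold, Louvain
community count) in the slow-oscillation band (< 2 Hz).

Coherence values are Fisher-z transformed (atanh of the magnitude
coherence) before averaging and back-transformed afterwards, avoiding the
skew of the bounded coherence distribution.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
from scipy.signal import hilbert, iirpeak, lfilter

from . import connectome as conn_mod
from .mesh import HemisphereMesh, geodesic_distances

logger = logging.getLogger(__name__)

SO_BAND_HZ = 2.0
DEFAULT_THRESHOLD = 0.3


def default_bands(f_lo: float = 0.5, f_hi: float = 20.0, step: float = 0.5) -> np.ndarray:
    """(n_bands, 2) array of (center, 3 dB bandwidth) pairs.

    Bandwidth grows with frequency (quarter of the center, floored at 0.5
    Hz); the grid is fully overridable.
    """
    centers = np.arange(f_lo, f_hi + 1e-9, step)
    bw = np.maximum(0.5, centers / 4.0)
    return np.column_stack([centers, bw])


@dataclasses.dataclass
class ParcelSignalSet:
    signals: np.ndarray          # (parcels, samples)
    fs_hz: float
    distance_mm: np.ndarray      # (parcels, parcels) fiber distances
    snr: float | None


@dataclasses.dataclass
class CoherenceLandscape:
    freqs_hz: np.ndarray                 # band centers
    coherence: np.ndarray                # (bands, parcels, parcels) MSC
    distance_mm: np.ndarray
    lambda_mm: np.ndarray | None = None  # per band
    alpha: np.ndarray | None = None
    percent_connected: float | None = None
    n_communities: int | None = None

    @property
    def lambda_05(self) -> float:
        i = int(np.argmin(np.abs(self.freqs_hz - 0.5)))
        return float(self.lambda_mm[i])

    @property
    def mean_alpha_so(self) -> float:
        m = self.freqs_hz < SO_BAND_HZ
        return float(np.nanmean(self.alpha[m]))


def parcel_distance_table(mesh: HemisphereMesh, fiber: bool = True) -> np.ndarray:
    """Pairwise parcel distances: geodesic between parcel centroid columns,
    optionally mapped to fiber length."""
    from .mesh import parcel_centroids

    k = mesh.n_parcels
    cent = parcel_centroids(mesh)
    centroid_cols = np.array([
        mesh.parcel_members(p)[
            int(np.argmin(np.linalg.norm(mesh.vertices[mesh.parcel_members(p)] - cent[p], axis=1)))
        ]
        for p in range(k)
    ])
    d = geodesic_distances(mesh, centroid_cols)[:, centroid_cols]
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    if fiber:
        d = conn_mod.geodesic_to_fiber(d)
        np.fill_diagonal(d, 0.0)
    return d


def parcel_signals(
    parcel_v: np.ndarray,
    fs_hz: float,
    mesh: HemisphereMesh,
    snr: float | None = 5.0,
    seed: int = 0,
) -> ParcelSignalSet:
    """Parcel-average voltages with additive white Gaussian noise.

    ``snr`` is the signal-power to noise-power ratio (default 5, emulating
    depth-electrode recording noise); None disables the noise.
    """
    x = np.asarray(parcel_v, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected (samples, parcels) parcel voltages")
    if x.shape[1] > x.shape[0]:
        raise ValueError("more parcels than samples; is the matrix transposed?")
    x = x.T.copy()  # (parcels, samples)
    if np.any(np.all(x == 0, axis=1)):
        raise ValueError("empty parcel signal encountered")
    if snr is not None:
        rng = np.random.default_rng(seed)
        power = x.var(axis=1, keepdims=True)
        noise = rng.standard_normal(x.shape) * np.sqrt(power / snr)
        x = x + noise
    return ParcelSignalSet(
        signals=x, fs_hz=fs_hz, distance_mm=parcel_distance_table(mesh), snr=snr
    )


# ---------------------------------------------------------------------------
# filterbank and coherence
# ---------------------------------------------------------------------------

def resonator_coefficients(f0: float, bw: float, fs: float):
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    if f0 >= fs / 2:
        raise ValueError("band center above Nyquist")
    return iirpeak(f0 / (fs / 2.0), f0 / bw)


def filterbank(signals: np.ndarray, fs_hz: float, bands: np.ndarray) -> np.ndarray:
    """Apply one second-order resonator per band.  Returns
    (bands, channels, samples)."""
    x = np.asarray(signals, dtype=np.float64)
    out = np.empty((len(bands), *x.shape))
    for i, (f0, bw) in enumerate(bands):
        b, a = resonator_coefficients(f0, bw, fs_hz)
        out[i] = lfilter(b, a, x, axis=-1)
    return out


def cross_spectral_matrix(narrow: np.ndarray) -> np.ndarray:
    """Cross-spectral matrix of one narrow-band signal set: covariance of the
    analytic signals.  Input (channels, samples), output (channels, channels)
    complex."""
    z = hilbert(narrow, axis=-1)
    z = z - z.mean(axis=-1, keepdims=True)
    return (z @ z.conj().T) / z.shape[-1]


def msc_from_csm(csm: np.ndarray) -> np.ndarray:
    """Magnitude-squared coherence from a cross-spectral matrix; rows of
    zero-variance channels are set to NaN."""
    auto = np.real(np.diag(csm)).copy()
    bad = auto <= 0
    if bad.any():
        logger.warning("%d zero-variance channels in coherence computation", int(bad.sum()))
        auto[bad] = np.nan
    denom = np.outer(auto, auto)
    msc = (np.abs(csm) ** 2) / denom
    msc = np.clip(msc, 0.0, 1.0)
    np.fill_diagonal(msc, 1.0)
    msc[bad, :] = np.nan
    msc[:, bad] = np.nan
    return msc


def coherence_matrices(
    signals: ParcelSignalSet, bands: np.ndarray | None = None
) -> CoherenceLandscape:
    """Per-band MSC matrices from a parcel signal set."""
    if bands is None:
        bands = default_bands()
    n_cyc = signals.signals.shape[1] / signals.fs_hz * bands[:, 0]
    if np.any(n_cyc < 10):
        raise ValueError("window shorter than 10 cycles of the lowest band")
    narrow = filterbank(signals.signals, signals.fs_hz, bands)
    coh = np.stack([msc_from_csm(cross_spectral_matrix(nb)) for nb in narrow])
    return CoherenceLandscape(
        freqs_hz=bands[:, 0], coherence=coh, distance_mm=signals.distance_mm
    )


# ---------------------------------------------------------------------------
# Fisher z and exponential fits
# ---------------------------------------------------------------------------

def fisher_z(msc):
    """Variance-stabilizing transform of magnitude coherence: atanh(sqrt(MSC))."""
    return np.arctanh(np.sqrt(np.clip(msc, 0.0, 1.0 - 1e-15)))


def inverse_fisher_z(z):
    return np.tanh(z) ** 2


def fit_exponential(
    landscape: CoherenceLandscape,
    domain_mm: tuple[float, float] = (0.0, 100.0),
) -> CoherenceLandscape:
    """Exponential coherence-vs-distance fit per band on the 0-100 mm domain.

    OLS of log(coherence) on distance with an intercept; the length constant
    is -1/slope and the scaling term (maximum coherence) is exp(intercept).
    A non-negative slope yields an infinite length constant.
    """
    k = landscape.coherence.shape[1]
    iu = np.triu_indices(k, 1)
    d = landscape.distance_mm[iu]
    sel = (d >= domain_mm[0]) & (d <= domain_mm[1])
    if sel.sum() < 10:
        raise ValueError("fewer than 10 parcel pairs in the fit domain")
    lambdas, alphas = [], []
    for m in landscape.coherence:
        c = m[iu][sel]
        ok = np.isfinite(c) & (c > 0)
        x, y = d[sel][ok], np.log(c[ok])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            logger.warning("non-negative distance slope; length constant set to inf")
            lambdas.append(np.inf)
        else:
            lambdas.append(-1.0 / slope)
        alphas.append(min(np.exp(intercept), 1.0))
    landscape.lambda_mm = np.array(lambdas)
    landscape.alpha = np.array(alphas)
    return landscape


# ---------------------------------------------------------------------------
# functional connectivity
# ---------------------------------------------------------------------------

def functional_connectivity(
    landscape: CoherenceLandscape,
    threshold: float = DEFAULT_THRESHOLD,
    distance_scaling: str = "none",
    pair_mask: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[float, int]:
    """Percent-connected and Louvain community count in the SO band.

    The SO-band (< 2 Hz) MSC matrices are averaged through the Fisher-z
    domain; the result is optionally scaled by the pair distances
    ({'none', 'multiply', 'divide'}) and masked by a boolean pair mask
    (emulating recording sparsity) before thresholding.
    """
    m = landscape.freqs_hz < SO_BAND_HZ
    if not m.any():
        raise ValueError("no SO-band (< 2 Hz) matrices available")
    avg = inverse_fisher_z(fisher_z(landscape.coherence[m]).mean(axis=0))
    np.fill_diagonal(avg, 1.0)
    if distance_scaling == "multiply":
        scaled = avg * landscape.distance_mm
    elif distance_scaling == "divide":
        scaled = avg / np.maximum(landscape.distance_mm, 1e-9)
    elif distance_scaling == "none":
        scaled = avg
    else:
        raise ValueError("distance_scaling must be none|multiply|divide")
    k = scaled.shape[0]
    iu = np.triu_indices(k, 1)
    valid = np.isfinite(scaled[iu])
    if pair_mask is not None:
        valid &= pair_mask[iu]
    vals = scaled[iu][valid]
    if vals.size == 0:
        landscape.percent_connected = 0.0
        landscape.n_communities = k
        return 0.0, k
    above = vals > threshold
    pct = 100.0 * above.mean()
    adj = np.zeros((k, k))
    sel = np.zeros(len(iu[0]), dtype=bool)
    sel[np.flatnonzero(valid)[above]] = True
    adj[iu[0][sel], iu[1][sel]] = scaled[iu][sel]
    adj += adj.T
    g = nx.from_numpy_array(adj)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    if g.number_of_edges() == 0:
        n_comm = k
    else:
        comms = nx.community.louvain_communities(g, seed=seed)
        n_comm = len(comms) + (k - g.number_of_nodes())
    landscape.percent_connected = float(pct)
    landscape.n_communities = int(n_comm)
    return float(pct), int(n_comm)


def cmd(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation matrix distance: 1 - trace(AB) / (||A||_F ||B||_F)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("matrices must share a shape")
    na, nb = np.linalg.norm(a, "fro"), np.linalg.norm(b, "fro")
    if na == 0 or nb == 0:
        raise ValueError("zero-norm matrix in CMD")
    return float(1.0 - np.trace(a @ b) / (na * nb))


# ---------------------------------------------------------------------------
# adaptive epoch sampling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AdaptiveResult:
    csm: np.ndarray               # (bands, ch, ch) mean cross-spectral matrices
    coherence: np.ndarray         # derived MSC
    converged: bool
    minutes_used: list


def adaptive_estimate(
    chunk_source,
    fs_hz: float,
    bands: np.ndarray,
    seed: int = 0,
    pad_s: float = 1.5,
    cmd_tol: float = 1e-5,
    n_repeats: int = 10,
    max_minutes: int = 60,
) -> AdaptiveResult:
    """Adaptive estimation of stable coherence matrices from 1-minute chunks.

    ``chunk_source(rng)`` must return a (channels, samples) array covering one
    minute plus ``pad_s`` of padding on each side (used for filtering and
    analytic-signal extraction, then trimmed), or None when exhausted.
    Incoming minutes are rejected (from the third minute on) when their CMD
    to the cumulative estimate exceeds the running mean by three standard
    deviations; the estimate has converged when adding a minute moves the
    cumulative coherence by less than ``cmd_tol`` in CMD.  The whole
    procedure runs ``n_repeats`` times and the cross-spectral matrices are
    averaged.
    """
    rng = np.random.default_rng(seed)
    pad = int(round(pad_s * fs_hz))
    all_csms = []
    converged_all = True
    minutes_used = []

    for rep in range(n_repeats):
        csum = None
        n_min = 0
        history = []
        converged = False
        for _ in range(max_minutes):
            chunk = chunk_source(rng)
            if chunk is None:
                break
            narrow = filterbank(chunk, fs_hz, bands)
            z = hilbert(narrow, axis=-1)[..., pad:-pad if pad else None]
            z = z - z.mean(axis=-1, keepdims=True)
            csm_inc = np.einsum("bct,bdt->bcd", z, z.conj()) / z.shape[-1]
            if csum is not None and n_min >= 2:
                d_inc = np.mean([cmd(np.abs(csum[i] / n_min), np.abs(csm_inc[i]))
                                 for i in range(len(bands))])
                if len(history) >= 2:
                    mu, sd = np.mean(history), np.std(history)
                    if d_inc > mu + 3 * sd:
                        history.append(d_inc)
                        continue  # reject outlier minute
                history.append(d_inc)
            elif csum is not None:
                d_inc = np.mean([cmd(np.abs(csum[i] / n_min), np.abs(csm_inc[i]))
                                 for i in range(len(bands))])
                history.append(d_inc)
            if csum is None:
                csum = csm_inc
                n_min = 1
                continue
            new = csum + csm_inc
            d_cum = np.mean([
                cmd(np.abs(csum[i] / n_min), np.abs(new[i] / (n_min + 1)))
                for i in range(len(bands))
            ])
            csum, n_min = new, n_min + 1
            if d_cum < cmd_tol:
                converged = True
                break
        if csum is None:
            raise ValueError("chunk source yielded no data")
        all_csms.append(csum / n_min)
        minutes_used.append(n_min)
        converged_all &= converged

    mean_csm = np.mean(all_csms, axis=0)
    coh = np.stack([msc_from_csm(mean_csm[i]) for i in range(len(bands))])
    if not converged_all:
        logger.warning("adaptive coherence estimate did not fully converge")
    return AdaptiveResult(csm=mean_csm, coherence=coh,
                          converged=converged_all, minutes_used=minutes_used)
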