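"""Observables of envelope dynamics: Envelope FC, metastability, CCD, KS fit.

Envelope FC is the region-by-region Pearson correlation of the slow envelope
components over the whole retained record.  Metastability is the standard
deviation over time of the Kuramoto order parameter

    R(t) = | sum_k exp(i * phi_k(t)) | / n

of the envelope phases: R = 1 under full synchronization, near zero under
complete independence, and its variability indexes switching among partially
synchronized states.  Coherence Connectivity Dynamics (CCD) is the
time-by-time matrix of cosine similarities between instantaneous coherence
vectors V(t), where V(t) holds cos|phi_i(t) - phi_j(t)| for all undirected
region pairs (row-major upper-triangle order).  Distributions of
upper-triangle CCD values are compared with the two-sample
Kolmogorov-Smirnov distance, the model-fitting objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .envelopes import CarrierBand
from .errors import StructuralError, ValidationError


@dataclass
class EnvelopeFC:
    """Pearson correlations of slow envelopes; symmetric, unit diagonal."""

    matrix: np.ndarray
    band: CarrierBand

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def mean_offdiagonal(self) -> float:
        """Mean FC over region pairs (the 'mean value of the FC matrix')."""
        return float(np.nanmean(self.upper_triangle()))


@dataclass
class OrderParameterSeries:
    """Kuramoto order parameter over time and its standard deviation."""

    R: np.ndarray
    metastability: float


@dataclass
class CCDMatrix:
    """Cosine similarities between coherence vectors at all time pairs.

    ``coherence_vectors`` (the explicit V(t) rows, shape ``(T, n*(n-1)/2)``)
    is materialized lazily on first access; the similarity matrix itself is
    computed through the phasor identity in :func:`compute_ccd`.
    """

    matrix: np.ndarray
    phases: np.ndarray  # (n, T) envelope phases the matrix was built from
    _vectors: np.ndarray | None = None

    @property
    def coherence_vectors(self) -> np.ndarray:
        if self._vectors is None:
            n = self.phases.shape[0]
            i, j = np.triu_indices(n, k=1)
            self._vectors = np.cos(self.phases[i, :] - self.phases[j, :]).T
        return self._vectors

    @property
    def n_times(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle values (the fitted distribution)."""
        iu = np.triu_indices(self.n_times, k=1)
        vals = self.matrix[iu]
        return vals[np.isfinite(vals)]


def envelope_fc(slow_envelopes: np.ndarray, band: CarrierBand) -> EnvelopeFC:
    """Pairwise Pearson correlation of slow envelopes over the full record.

    Zero-variance regions yield NaN rows/columns (flagged undefined, with a
    warning) rather than a silent zero.  Averaging across subjects/runs is a
    plain mean over EnvelopeFC matrices, done by the caller.
    """
    x = np.atleast_2d(np.asarray(slow_envelopes, dtype=float))
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 samples for a correlation")
    sd = x.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(x)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance region(s): correlations "
            "flagged as NaN",
            stacklevel=2,
        )
        m[degenerate, :] = np.nan
        m[:, degenerate] = np.nan
    np.fill_diagonal(m, 1.0)
    return EnvelopeFC(m, band)


def kuramoto_order(phases: np.ndarray) -> float | np.ndarray:
    """Modulus of the mean unit phasor over regions.

    Accepts a length-n vector (one time point) or an (n, T) matrix, in which
    case a length-T series is returned.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValidationError("kuramoto_order of empty input")
    if not np.all(np.isfinite(phases)):
        raise ValidationError("phases must be finite")
    r = np.abs(np.exp(1j * phases).mean(axis=0))
    return float(r) if np.isscalar(r) or r.ndim == 0 else r


def metastability(envelope_phases: np.ndarray) -> OrderParameterSeries:
    """Standard deviation over time of the Kuramoto order parameter.

    Uses the population standard deviation (ddof=0); at the record lengths
    of interest the distinction from ddof=1 is immaterial, but it is fixed
    for reproducibility.
    """
    phases = np.atleast_2d(np.asarray(envelope_phases, dtype=float))
    if phases.shape[1] < 2:
        raise ValidationError("need at least 2 time samples")
    R = kuramoto_order(phases)
    return OrderParameterSeries(R=R, metastability=float(np.std(R)))


def coherence_vector(phases: np.ndarray) -> np.ndarray:
    """cos|phi_i - phi_j| over undirected pairs i<j, row-major triangle order.

    Pair order is (0,1), (0,2), ..., (0,n-1), (1,2), ... — fixed so
    coherence vectors are comparable across runs.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 1 or phases.size < 2:
        raise StructuralError("coherence_vector expects >= 2 phases at one time")
    i, j = np.triu_indices(phases.size, k=1)
    return np.cos(phases[i] - phases[j])


def compute_ccd(envelope_phases: np.ndarray) -> CCDMatrix:
    """CCD(t1, t2) = V(t1).V(t2) / (||V(t1)|| ||V(t2)||) for all time pairs.

    The Gram matrix of the coherence vectors is evaluated through a phasor
    identity: with Z_tk = exp(i*phi_k(t)),

        V(t).V(t') = ( |(Z Z^H)_tt'|^2 + |(Z Z^T)_tt'|^2 - 2n ) / 4,

    which costs O(T^2 n) instead of O(T^2 n^2) (three real matrix products
    on the cos/sin parts).  Zero-norm coherence vectors give NaN
    rows/columns (flagged undefined); the diagonal is exactly 1.
    """
    phases = np.atleast_2d(np.asarray(envelope_phases, dtype=float))
    n, T = phases.shape
    if n < 2 or T < 2:
        raise ValidationError("compute_ccd needs >= 2 regions and >= 2 samples")

    cr = np.cos(phases.T)  # (T, n)
    si = np.sin(phases.T)
    A = cr @ cr.T
    B = si @ si.T
    M = cr @ si.T
    asym = M - M.T
    # |Z Z^H|^2 = (A+B)^2 + (M^T-M)^2 ; |Z Z^T|^2 = (A-B)^2 + (M+M^T)^2
    dots = ((A + B) ** 2 + asym**2 + (A - B) ** 2 + (M + M.T) ** 2 - 2.0 * n) / 4.0

    norms = np.sqrt(np.clip(np.diag(dots), 0.0, None))
    bad = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ccd = dots / np.outer(norms, norms)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} zero-norm coherence vector(s): CCD entries "
            "flagged as NaN",
            stacklevel=2,
        )
        ccd[bad, :] = np.nan
        ccd[:, bad] = np.nan
    np.clip(ccd, -1.0, 1.0, out=ccd)
    np.fill_diagonal(ccd, 1.0)
    return CCDMatrix(matrix=ccd, phases=phases)


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_x |F_a(x) - F_b(x)|.

    Direct empirical-CDF evaluation via searchsorted; suitable for the
    ~1e6-value pooled CCD samples used in fitting.
    """
    a = np.sort(np.asarray(sample_a, dtype=float).ravel())
    b = np.sort(np.asarray(sample_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValidationError("KS statistic of an empty sample")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_distance(ccd_a: "CCDMatrix | np.ndarray", ccd_b: "CCDMatrix | np.ndarray") -> float:
    """KS distance between the upper-triangle CCD value distributions.

    Accepts CCD matrices or pre-pooled value arrays (for targets pooled over
    runs/subjects the caller concatenates triangles first).
    """
    a = _ccd_values(ccd_a)
    b = _ccd_values(ccd_b)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 off-diagonal CCD values per side")
    return ks_statistic(a, b)


def _ccd_values(obj) -> np.ndarray:
    if isinstance(obj, CCDMatrix):
        return obj.upper_triangle()
    arr = np.asarray(obj, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def amplitude_synchrony_correlation(
    signal: np.ndarray,
    rate: float,
    band: CarrierBand,
    trim_seconds: float = 1.0,
    filter_order: int = 4,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Coupling between mean band-limited amplitude and carrier-phase synchrony.

    Band-passes the signal, takes carrier phases and amplitudes from the
    analytic signal, and correlates the node-mean amplitude with the Kuramoto
    order parameter of the carrier phases over time.  In the critical Hopf
    network the two are strongly positively coupled: excursions toward the
    oscillatory regime raise amplitude and zero-lag synchrony together.

    Returns ``(r, R_t, mean_amplitude)`` after edge trimming.
    """
    from .envelopes import bandpass, hilbert_envelope

    nb = bandpass(signal, rate, band, order=filter_order)
    env, phase = hilbert_envelope(nb, rate, trim_seconds=trim_seconds)
    k = int(round(trim_seconds * rate))
    sl = np.s_[:, k:-k] if k else np.s_[:, :]
    R_t = kuramoto_order(phase[sl])
    mean_amp = env[sl].mean(axis=0)
    r = float(np.corrcoef(mean_amp, R_t)[0, 1])
    return r, R_t, mean_amp


def fc_similarity(fc_a: EnvelopeFC, fc_b: EnvelopeFC) -> float:
    """Pearson correlation of the vectorized FC upper triangles (no diagonal)."""
    if fc_a.n != fc_b.n:
        raise StructuralError("FC matrices have different region counts")
    a = fc_a.upper_triangle()
    b = fc_b.upper_triangle()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn("degenerate FC triangle: similarity undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
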