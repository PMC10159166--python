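"""Higher-order statistical and nonlinear features of signal blocks.

Fifteen features are computed per fixed-length window of the filtered
plant electrical signal:

======================  =====================================================
mean, variance          first two moments (population variance, /N)
skewness, kurtosis      standardized central moments k = 3, 4 (Gaussian: 0, 3)
superskewness           standardized 5th central moment (Gaussian: 0)
superflatness           standardized 6th central moment (Gaussian: 15)
iqr                     interquartile range (linear-interpolation quartiles)
fano                    Fano factor sigma^2 / mu
hjorth_mobility         sqrt(var(dx) / var(x))
hjorth_complexity       mobility(dx) / mobility(x)
dfa_alpha               detrended-fluctuation scaling exponent
hurst                   rescaled-range (R/S) Hurst exponent
wp_entropy              Shannon entropy of wavelet-packet leaf energies
spectral_power          average power (1/N) sum x^2 (Parseval)
corr_dim                Grassberger-Procaccia correlation dimension
======================  =====================================================

Degenerate inputs (constant blocks, near-zero mean for the Fano factor)
yield NaN for the affected features rather than raising inside the table
pipeline; the downstream outlier stage drops flagged rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

FEATURE_NAMES = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "iqr",
    "hjorth_mobility",
    "hjorth_complexity",
    "dfa_alpha",
    "hurst",
    "wp_entropy",
    "spectral_power",
    "superskewness",
    "superflatness",
    "fano",
    "corr_dim",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Estimator settings for the parameterized features.

    The window-based estimators (DFA, R/S, correlation dimension,
    wavelet-packet entropy) have no single canonical parameterization;
    these defaults follow common practice for ~1000-sample biosignal
    windows and every one is overridable.
    """

    dfa_min_box: int = 4
    dfa_max_box_frac: float = 0.25   # largest box = N * frac
    dfa_n_boxes: int = 12
    rs_min_window: int = 8
    rs_max_window_frac: float = 0.5
    rs_n_windows: int = 10
    wavelet: str = "db4"
    wp_level: int = 3
    embed_dim: int = 5
    embed_tau: int = 1
    corr_dim_n_radii: int = 20

    def __post_init__(self) -> None:
        if self.dfa_min_box < 4:
            raise ValueError("dfa_min_box must be >= 4")
        if self.wp_level < 1:
            raise ValueError("wp_level must be >= 1")
        if self.embed_dim < 2 or self.embed_tau < 1:
            raise ValueError("need embed_dim >= 2 and embed_tau >= 1")


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def moments(block: np.ndarray) -> dict[str, float]:
    """Mean, population variance, standardized moments 3..6, IQR, Fano.

    Standardized central moments E[(x-mu)^k] / sigma^k are reported for
    k = 3..6 (skewness, kurtosis, superskewness, superflatness); on a
    Gaussian these are 0, 3, 0, 15. A constant block leaves the
    standardized moments NaN; |mean| < 1e-12 leaves the Fano factor NaN.
    """
    x = np.asarray(block, float)
    if x.size < 4:
        raise ValueError("block must have at least 4 samples")
    mu = x.mean()
    centered = x - mu
    var = np.mean(centered**2)
    q1, q3 = np.percentile(x, [25, 75])
    out = {"mean": mu, "variance": var, "iqr": q3 - q1}
    if var > 0:
        sigma = np.sqrt(var)
        for name, k in (("skewness", 3), ("kurtosis", 4),
                        ("superskewness", 5), ("superflatness", 6)):
            out[name] = np.mean(centered**k) / sigma**k
    else:
        out.update(skewness=np.nan, kurtosis=np.nan,
                   superskewness=np.nan, superflatness=np.nan)
    out["fano"] = var / mu if abs(mu) >= 1e-12 else np.nan
    return out


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------

def hjorth(block: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity.

    mobility = sqrt(var(dx)/var(x)); complexity = mobility(dx)/mobility(x)
    with dx the first difference. White noise has mobility sqrt(2) and
    complexity sqrt(3)/sqrt(2); a slow sinusoid of frequency f sampled at
    fs has mobility 2 sin(pi f / fs).
    """
    x = np.asarray(block, float)
    if x.size < 3:
        raise ValueError("block must have at least 3 samples")
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_x, var_dx, var_ddx = x.var(), dx.var(), ddx.var()
    if var_x == 0 or var_dx == 0:
        raise ValueError("degenerate input: zero variance")
    mobility = np.sqrt(var_dx / var_x)
    complexity = np.sqrt(var_ddx / var_dx) / mobility
    return mobility, complexity


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def _log_spaced_ints(lo: int, hi: int, num: int) -> np.ndarray:
    vals = np.unique(np.round(np.geomspace(lo, hi, num)).astype(int))
    return vals[(vals >= lo) & (vals <= hi)]

def dfa_alpha(block: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> float:
    """DFA scaling exponent with linear detrending.

    The mean-removed series is integrated; for log-spaced box sizes the
    RMS of residuals around a per-box linear fit gives F(n); alpha is
    the least-squares slope of log F(n) vs log n. White noise scales
    with alpha ~ 0.5, a random walk with alpha ~ 1.5, and fGn with
    alpha = H.
    """
    x = np.asarray(block, float)
    if x.size < 256:
        raise ValueError("DFA needs at least 256 samples")
    y = np.cumsum(x - x.mean())
    n_max = max(cfg.dfa_min_box + 1, int(x.size * cfg.dfa_max_box_frac))
    boxes = _log_spaced_ints(cfg.dfa_min_box, n_max, cfg.dfa_n_boxes)
    if boxes.size < 4:
        raise ValueError("fewer than 4 usable DFA box sizes")
    flucts = np.empty(boxes.size)
    for i, n in enumerate(boxes):
        n_seg = y.size // n
        segs = y[: n_seg * n].reshape(n_seg, n)
        t = np.arange(n)
        # per-segment linear fit, vectorized over segments
        coef = np.polynomial.polynomial.polyfit(t, segs.T, 1)
        trend = coef[0][:, None] + coef[1][:, None] * t
        flucts[i] = np.sqrt(np.mean((segs - trend) ** 2))
    if np.any(flucts <= 0):
        raise ValueError("degenerate input: zero detrended fluctuation")
    slope = np.polyfit(np.log(boxes), np.log(flucts), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Rescaled-range Hurst exponent
# ---------------------------------------------------------------------------

def hurst_rs(block: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> float:
    """Classical rescaled-range (R/S) estimate of the Hurst exponent.

    For log-spaced window sizes w the series is cut into segments; per
    segment, R is the range of the cumulative mean-removed sum and S the
    standard deviation; H is the slope of log mean(R/S) against log w.
    Zero-variance segments are skipped.
    """
    x = np.asarray(block, float)
    if x.size < 256:
        raise ValueError("R/S needs at least 256 samples")
    w_max = max(cfg.rs_min_window + 1, int(x.size * cfg.rs_max_window_frac))
    windows = _log_spaced_ints(cfg.rs_min_window, w_max, cfg.rs_n_windows)
    sizes, ratios = [], []
    for w in windows:
        n_seg = x.size // w
        segs = x[: n_seg * w].reshape(n_seg, w)
        dev = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        rng = z.max(axis=1) - z.min(axis=1)
        std = segs.std(axis=1)
        ok = std > 0
        if not np.any(ok):
            continue
        sizes.append(w)
        ratios.append(np.mean(rng[ok] / std[ok]))
    if len(sizes) < 2:
        raise ValueError("all R/S windows degenerate")
    slope = np.polyfit(np.log(sizes), np.log(ratios), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Wavelet-packet entropy
# ---------------------------------------------------------------------------

def wavelet_packet_entropy(block: np.ndarray,
                           cfg: FeatureConfig = FeatureConfig()) -> float:
    """Shannon entropy of normalized wavelet-packet leaf energies.

    A full decomposition to ``cfg.wp_level`` yields 2^level leaf bands;
    with p_j the fraction of total energy in leaf j, the entropy is
    H = -sum p_j ln p_j, in [0, ln 2^level]. White signals spread energy
    across all bands (H near the maximum); a narrowband tone
    concentrates it (H near 0).
    """
    x = np.asarray(block, float)
    wp = pywt.WaveletPacket(data=x, wavelet=cfg.wavelet, mode="symmetric",
                            maxlevel=cfg.wp_level)
    energies = np.array([
        np.sum(np.asarray(node.data) ** 2)
        for node in wp.get_level(cfg.wp_level, order="natural")
    ])
    total = energies.sum()
    if total <= 0:
        raise ValueError("degenerate input: zero total energy")
    p = energies / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# Average spectral power
# ---------------------------------------------------------------------------

def spectral_power(block: np.ndarray) -> float:
    """Average power (1/N) sum x^2 (equals mean periodogram energy)."""
    x = np.asarray(block, float)
    if x.size < 2:
        raise ValueError("block must have at least 2 samples")
    return float(np.mean(x**2))


# ---------------------------------------------------------------------------
# Correlation dimension
# ---------------------------------------------------------------------------

def _delay_embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_vec = x.size - (m - 1) * tau
    if n_vec < 2:
        raise ValueError("series too short for the requested embedding")
    return np.column_stack([x[i * tau: i * tau + n_vec] for i in range(m)])


def correlation_sum(emb: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Fraction of distinct point pairs of the embedding closer than r."""
    from scipy.spatial.distance import pdist

    d = pdist(emb)
    return np.array([(d < r).mean() for r in radii])


def correlation_dimension(block: np.ndarray,
                          cfg: FeatureConfig = FeatureConfig()) -> float:
    """Grassberger-Procaccia correlation dimension d_c.

    The block is delay-embedded (default m=5, tau=1); the correlation
    sum C(r) is evaluated on a log radius grid spanning 1%-50% of the
    attractor diameter and d_c is the least-squares slope of
    log C vs log r over the middle third of the grid. A limit cycle
    (noise-free sinusoid) gives d_c near 1; iid noise fills the
    embedding space. All-equal points give d_c = 0 by convention.
    """
    from scipy.spatial.distance import pdist

    x = np.asarray(block, float)
    if x.size < 512:
        raise ValueError("correlation dimension needs at least 512 samples")
    emb = _delay_embed(x, cfg.embed_dim, cfg.embed_tau)
    d = pdist(emb)
    diameter = d.max()
    if diameter == 0:
        return 0.0
    radii = np.geomspace(0.01 * diameter, 0.5 * diameter, cfg.corr_dim_n_radii)
    c = np.array([(d < r).mean() for r in radii])
    third = cfg.corr_dim_n_radii // 3
    sel = slice(third, 2 * third + 1)
    r_sel, c_sel = radii[sel], c[sel]
    ok = c_sel > 0
    if ok.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(r_sel[ok]), np.log(c_sel[ok]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_features(block, cfg: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """All fifteen features for one block (array or SignalBlock).

    Component failures on degenerate input are propagated as NaN so a
    flagged row survives to the outlier-removal stage, which drops it.
    """
    samples = getattr(block, "samples", block)
    out = moments(samples)
    try:
        out["hjorth_mobility"], out["hjorth_complexity"] = hjorth(samples)
    except ValueError:
        out["hjorth_mobility"] = out["hjorth_complexity"] = np.nan
    for name, fn in (("dfa_alpha", dfa_alpha), ("hurst", hurst_rs),
                     ("wp_entropy", wavelet_packet_entropy),
                     ("corr_dim", correlation_dimension)):
        try:
            out[name] = fn(samples, cfg)
        except ValueError:
            out[name] = np.nan
    out["spectral_power"] = spectral_power(samples)
    return {name: out[name] for name in FEATURE_NAMES}


def extract_table(blocks, cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Feature table for a list of SignalBlocks.

    Columns: block_id, stimulus, species, then the 15 features in
    :data:`FEATURE_NAMES` order.
    """
    rows = []
    for b in blocks:
        row = {"block_id": b.block_id, "stimulus": b.stimulus, "species": b.species}
        row.update(extract_features(b.samples, cfg))
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["normalized"] = False
    return table


def feature_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Constant features have undefined correlations; those entries are NaN.
    """
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    values = table[cols].to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise ValueError("table contains non-finite feature values")
    return pd.DataFrame(np.corrcoef(values, rowvar=False), index=cols, columns=cols)
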