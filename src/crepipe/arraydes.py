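"""Two-color microarray differential expression.

The analysis stage mirrors the classic two-color workflow for a glucose
vs. ribose co-hybridization design: per-spot log-ratios (M) oriented so
positive M always means higher expression on ribose regardless of dye
orientation, within-array loess normalization of M on A, between-array
scale normalization, a consensus within-array probe-replicate correlation,
gene-wise generalized least squares under compound symmetry, empirical-
Bayes variance moderation, Benjamini–Hochberg FDR adjustment, and
threshold classification (q < 0.01 and |log2fc| > 0.5; |log2fc| > 1.0
flagged as strong).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Upper cap on the prior degrees of freedom; beyond this d0 is treated as
#: infinite (all gene variances shrunk fully to the prior).
D0_CAP = 1e6


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: d0 prior degrees of freedom, s0_2 prior variance."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s0_2 > 0:
            raise ValueError("s0_2 must be > 0")


# ---------------------------------------------------------------------------
# Input handling

INTENSITY_COLUMNS = ["array_id", "spot_id", "probe_id", "locus", "ch1", "ch2", "excluded"]
DESIGN_COLUMNS = ["array_id", "strain", "bio_replicate", "ribose_channel", "is_dye_swap"]


def read_intensities(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = set(df["ribose_channel"]) - {"ch1", "ch2"}
    if bad:
        raise ValueError(f"ribose_channel must be ch1/ch2, got {sorted(bad)}")
    return df


def compute_ma(spots: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-spot M/A values with dye-orientation correction.

    M = log2(ribose intensity / glucose intensity); A = mean log2 intensity.
    Excluded spots and spots with a non-positive channel are dropped (the
    drop count is logged).
    """
    orient = design.set_index("array_id")["ribose_channel"]
    df = spots.copy()
    df = df[df["excluded"].astype(int) == 0]
    n_before = len(df)
    df = df[(df["ch1"] > 0) & (df["ch2"] > 0)]
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d spots with non-positive intensities", dropped)
    l1 = np.log2(df["ch1"].to_numpy(float))
    l2 = np.log2(df["ch2"].to_numpy(float))
    sign = np.where(df["array_id"].map(orient).to_numpy() == "ch2", 1.0, -1.0)
    out = df[["array_id", "spot_id", "probe_id", "locus"]].copy()
    out["M"] = sign * (l2 - l1)
    out["A"] = (l1 + l2) / 2.0
    return out.reset_index(drop=True)


def normalize_within(ma: pd.DataFrame, span: float = 0.4, min_spots: int = 20) -> pd.DataFrame:
    """Remove the intensity-dependent trend of M within each array.

    A loess curve of M on A (fraction ``span``) is subtracted per array;
    arrays with fewer than ``min_spots`` spots fall back to global
    median-centering with a warning.
    """
    out = ma.copy()
    for array_id, idx in out.groupby("array_id").groups.items():
        m = out.loc[idx, "M"].to_numpy(float)
        a = out.loc[idx, "A"].to_numpy(float)
        if len(idx) < min_spots:
            logger.warning(
                "array %s has %d spots; falling back to median centering",
                array_id,
                len(idx),
            )
            out.loc[idx, "M"] = m - np.median(m)
            continue
        delta = 0.01 * (a.max() - a.min())
        fitted = lowess(m, a, frac=span, delta=delta, return_sorted=False)
        out.loc[idx, "M"] = m - fitted
    return out


def normalize_between(ma: pd.DataFrame) -> pd.DataFrame:
    """Equalize the M scale (median absolute deviation) across arrays.

    Each array's M values are rescaled so all arrays share the geometric
    mean of the per-array MADs; single-array input is returned unchanged.
    """
    out = ma.copy()
    mads = out.groupby("array_id")["M"].apply(
        lambda m: stats.median_abs_deviation(m, scale="normal")
    )
    if len(mads) <= 1:
        return out
    if (mads <= 0).any():
        logger.warning("zero-MAD array(s) left unscaled: %s", list(mads[mads <= 0].index))
    target = np.exp(np.log(mads[mads > 0]).mean())
    factors = {a: (target / v if v > 0 else 1.0) for a, v in mads.items()}
    out["M"] = out["M"] * out["array_id"].map(factors)
    return out


# ---------------------------------------------------------------------------
# Probe-replicate correlation


def estimate_duplicate_correlation(
    ma: pd.DataFrame, min_genes: int = 50, trim: float = 0.1
) -> float:
    """Consensus within-array probe-replicate correlation.

    For each gene the within-array correlation is estimated as the one-way
    intraclass correlation over (array) groups of replicate spots; per-gene
    estimates are Fisher-z transformed, combined by a trimmed mean, and
    transformed back.  Degenerate (zero-variance) genes are skipped.
    """
    df = ma[["locus", "array_id", "M"]].copy()
    df["M2"] = df["M"] ** 2
    per_arr = df.groupby(["locus", "array_id"], sort=False).agg(
        k=("M", "size"), s=("M", "sum"), ss=("M2", "sum")
    )
    per_arr = per_arr[per_arr["k"] >= 2]
    k = per_arr["k"].to_numpy(float)
    mean = per_arr["s"].to_numpy(float) / k
    g = pd.DataFrame(
        {
            "locus": per_arr.index.get_level_values("locus"),
            "k": k,
            "k2": k**2,
            "s": per_arr["s"].to_numpy(float),
            "km2": k * mean**2,
            "ssw": per_arr["ss"].to_numpy(float) - k * mean**2,
        }
    ).groupby("locus", sort=False)
    agg = g.agg(
        n_arr=("k", "size"),
        n=("k", "sum"),
        sk2=("k2", "sum"),
        s=("s", "sum"),
        km2=("km2", "sum"),
        ssw=("ssw", "sum"),
    )
    agg = agg[agg["n_arr"] >= 2]
    n = agg["n"].to_numpy(float)
    grand = agg["s"].to_numpy(float) / n
    # between-group SS = sum k*mean^2 - N*grand^2
    ssb = agg["km2"].to_numpy(float) - n * grand**2
    ssw = agg["ssw"].to_numpy(float)
    df_b = agg["n_arr"].to_numpy(float) - 1.0
    df_w = n - agg["n_arr"].to_numpy(float)
    ok = (df_w > 0) & (df_b > 0) & (ssb + ssw > 0)
    msb = ssb[ok] / df_b[ok]
    msw = ssw[ok] / df_w[ok]
    k0 = (n[ok] - agg["sk2"].to_numpy(float)[ok] / n[ok]) / df_b[ok]  # avg group size
    denom = msb + (k0 - 1.0) * msw
    icc = np.where(denom > 0, (msb - msw) / np.where(denom > 0, denom, 1.0), 0.0)
    zs = np.arctanh(np.clip(icc, -0.999, 0.999))
    if zs.size < min_genes:
        raise ValueError(
            f"only {zs.size} genes usable for correlation estimation (< {min_genes})"
        )
    z = stats.trim_mean(zs, trim)
    return float(np.tanh(z))


# ---------------------------------------------------------------------------
# Gene-wise GLS fits


def fit_gene(m_by_array: Mapping[str, Sequence[float]], rho: float) -> dict:
    """Intercept-only GLS fit for one gene under compound symmetry.

    ``m_by_array`` maps array id → the gene's replicate M values on that
    array.  Replicates within an array share correlation ``rho``; arrays
    are independent.  Returns beta_hat, s2 (residual variance), df and v
    (unscaled variance of beta_hat, i.e. var(beta_hat) = s2 * v).
    """
    arrays = {a: np.asarray(vals, float) for a, vals in m_by_array.items() if len(vals)}
    arrays = {a: v[np.isfinite(v)] for a, v in arrays.items()}
    arrays = {a: v for a, v in arrays.items() if v.size}
    n_arrays = len(arrays)
    n_obs = sum(v.size for v in arrays.values())
    if n_arrays < 2:
        return {
            "beta_hat": np.nan,
            "s2": np.nan,
            "df": 0,
            "v": np.nan,
            "testable": False,
        }
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    # For block V_a = (1-rho) I + rho J:
    #   1' V_a^-1 1 = k / (1 - rho + k rho)
    #   1' V_a^-1 y = sum(y) / (1 - rho + k rho)
    #   y' V_a^-1 y = (sum(y^2) - rho/(1-rho+k rho) * sum(y)^2) / (1 - rho)
    sw = 0.0
    swy = 0.0
    q = 0.0
    for v in arrays.values():
        k = v.size
        denom = 1.0 - rho + k * rho
        sw += k / denom
        swy += v.sum() / denom
        if k == 1:
            q += v[0] ** 2
        else:
            q += (np.sum(v**2) - rho / denom * v.sum() ** 2) / (1.0 - rho)
    beta = swy / sw
    rss = q - beta**2 * sw
    df = n_obs - 1
    s2 = max(rss, 0.0) / df
    return {"beta_hat": beta, "s2": s2, "df": df, "v": 1.0 / sw, "testable": True}


def fit_genes(ma: pd.DataFrame, rho: float) -> pd.DataFrame:
    """Vectorized per-gene GLS fits over a normalized M/A table.

    Equivalent to calling :func:`fit_gene` per locus with the gene's
    per-array replicate values; genes observed on fewer than two arrays
    are returned untestable (NaN statistics).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    tmp = ma[["locus", "array_id", "M"]].copy()
    tmp["M2"] = tmp["M"] ** 2
    agg = tmp.groupby(["locus", "array_id"], sort=True).agg(
        k=("M", "size"), s=("M", "sum"), ss=("M2", "sum")
    )
    k = agg["k"].to_numpy(float)
    s = agg["s"].to_numpy(float)
    ss = agg["ss"].to_numpy(float)
    denom = 1.0 - rho + k * rho
    w = k / denom
    wy = s / denom
    qa = np.where(k == 1, ss, (ss - rho / denom * s**2) / (1.0 - rho))
    per_gene = pd.DataFrame(
        {
            "locus": agg.index.get_level_values("locus"),
            "k": k,
            "w": w,
            "wy": wy,
            "q": qa,
        }
    ).groupby("locus")
    out = per_gene.agg(
        n_arrays=("k", "size"),
        n_obs=("k", "sum"),
        sw=("w", "sum"),
        swy=("wy", "sum"),
        q=("q", "sum"),
    )
    beta = out["swy"] / out["sw"]
    df = out["n_obs"] - 1
    rss = (out["q"] - beta**2 * out["sw"]).clip(lower=0.0)
    s2 = rss / df
    testable = out["n_arrays"] >= 2
    res = pd.DataFrame(
        {
            "beta_hat": beta.where(testable),
            "s2": s2.where(testable),
            "df": df.where(testable, 0).astype(int),
            "v": (1.0 / out["sw"]).where(testable),
            "testable": testable,
        }
    )
    res.index.name = "locus"
    return res.reset_index()


# ---------------------------------------------------------------------------
# Empirical Bayes moderation


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return D0_CAP
    # starting value from the asymptotic 1/y behaviour
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if y <= 0:
            y = 1e-8
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Fit the scaled-inverse-chi-square prior to observed gene variances.

    Matches the first two moments of log s2 under the model
    s2 | sigma2 ~ sigma2 * chi2_df / df, sigma2 ~ s0_2 * d0 / chi2_d0,
    using digamma/trigamma identities; d0 above 1e6 is treated as infinite.
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    ok = np.isfinite(s2) & (df > 0) & (s2 > 0)
    if ok.sum() < 20:
        raise ValueError("need >= 20 genes with positive df and s2")
    s2 = s2[ok]
    df = df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1)
    # subtract the sampling variance of log s2 given sigma2
    resid_var = evar - np.mean(special.polygamma(1, df / 2.0))
    if resid_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    else:
        half_d0 = _trigamma_inverse(float(resid_var))
        d0 = 2.0 * half_d0
        if d0 >= D0_CAP:
            d0 = np.inf
            s0_2 = float(np.exp(emean))
        else:
            s0_2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationParams(d0=d0, s0_2=s0_2)


def moderate(
    fits: pd.DataFrame, params: ModerationParams | None = None
) -> tuple[ModerationParams, pd.DataFrame]:
    """Moderated t-statistics from gene fits.

    Posterior variance s_tilde2 = (d0*s0_2 + df*s2) / (d0 + df);
    t_mod = beta_hat / sqrt(s_tilde2 * v); two-sided p from t with
    d0 + df degrees of freedom.  Pass ``params`` with d0=0 is not allowed
    by :class:`ModerationParams`; use :func:`ordinary_t` for the
    unmoderated statistic.
    """
    if params is None:
        params = estimate_moderation(fits["s2"].to_numpy(), fits["df"].to_numpy())
    d0, s0_2 = params.d0, params.s0_2
    out = fits.copy()
    df = out["df"].to_numpy(float)
    s2 = out["s2"].to_numpy(float)
    if np.isinf(d0):
        s_tilde2 = np.full_like(s2, s0_2)
        df_total = np.full_like(df, np.inf)
    else:
        s_tilde2 = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = out["beta_hat"].to_numpy(float) / np.sqrt(s_tilde2 * out["v"].to_numpy(float))
        p = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(t)),
            2.0 * stats.t.sf(np.abs(t), df_total),
        )
    out["s_tilde2"] = s_tilde2
    out["t_mod"] = t
    out["p"] = p
    return params, out


def ordinary_t(fits: pd.DataFrame) -> pd.DataFrame:
    """Unmoderated gene-wise t-statistics (the d0 → 0 limit)."""
    out = fits.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t = out["beta_hat"] / np.sqrt(out["s2"] * out["v"])
        p = 2.0 * stats.t.sf(np.abs(t), out["df"])
    out["t_mod"] = t
    out["p"] = p
    return out


def adjust_bh(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (NaN-safe)."""
    p = np.asarray(list(p), float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify(
    results: pd.DataFrame,
    fdr: float = 0.01,
    lfc: float = 0.5,
    strong_lfc: float = 1.0,
) -> pd.DataFrame:
    """Assign regulation classes with strict thresholds.

    up ⟺ q < fdr and log2fc > lfc; down ⟺ q < fdr and log2fc < −lfc;
    strong ⟺ |log2fc| > strong_lfc (independent of q).
    """
    out = results.copy()
    q = out["q"].to_numpy(float)
    fc = out["log2fc"].to_numpy(float)
    cls = np.where(
        (q < fdr) & (fc > lfc), "up", np.where((q < fdr) & (fc < -lfc), "down", "unchanged")
    )
    cls = np.where(np.isfinite(q) & np.isfinite(fc), cls, "unchanged")
    out["class"] = cls
    out["strong"] = np.abs(fc) > strong_lfc
    return out


# ---------------------------------------------------------------------------
# Per-strain pipeline


def de_per_strain(
    spots: pd.DataFrame,
    design: pd.DataFrame,
    fdr: float = 0.01,
    lfc: float = 0.5,
    strong_lfc: float = 1.0,
    normalize: bool = True,
    rho: float | None = None,
    moderation: ModerationParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Full DE analysis, one independent fit per strain.

    Returns a dict strain → results table (locus, log2fc, t_mod, p, q,
    class, strong).  ``rho``/``moderation`` may be fixed for simulation
    studies; by default both are estimated from the data.
    """
    results: dict[str, pd.DataFrame] = {}
    for strain, des in design.groupby("strain"):
        sub = spots[spots["array_id"].isin(des["array_id"])]
        ma = compute_ma(sub, des)
        if normalize:
            ma = normalize_within(ma)
            ma = normalize_between(ma)
        strain_rho = estimate_duplicate_correlation(ma) if rho is None else rho
        fits = fit_genes(ma, strain_rho)
        _, mod = moderate(fits[fits["testable"]], moderation)
        mod = mod.rename(columns={"beta_hat": "log2fc"})
        mod["q"] = adjust_bh(mod["p"])
        mod = classify(mod, fdr=fdr, lfc=lfc, strong_lfc=strong_lfc)
        untestable = fits[~fits["testable"]][["locus"]].copy()
        for col in ["log2fc", "t_mod", "p", "q"]:
            untestable[col] = np.nan
        untestable["class"] = "unchanged"
        untestable["strong"] = False
        cols = ["locus", "log2fc", "t_mod", "p", "q", "class", "strong"]
        res = pd.concat([mod[cols], untestable[cols]], ignore_index=True)
        res.insert(1, "strain", strain)
        results[strain] = res.sort_values("locus").reset_index(drop=True)
    return results


def write_results(results: Mapping[str, pd.DataFrame], out_dir) -> list[str]:
    """Write one results TSV per strain; returns the written paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain, df in results.items():
        path = out_dir / f"de_{strain}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths.append(str(path))
    return paths
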