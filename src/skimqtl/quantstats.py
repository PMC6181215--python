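"""Variance components, heritability and trait correlations.

Balanced multi-environment trials only: environments fixed, genotypes and
genotype-by-environment random.  Components come from two-way ANOVA mean
squares solved through their expectations (MS_G = s2 + r*s2ge + r*e*s2g,
MS_GE = s2 + r*s2ge, MS_error = s2); the environment F-test uses the
replication-within-environment mean square as denominator.  Broad-sense
heritability is computed on an entry-mean basis:
H2 = s2g / [s2g + s2ge/e + s2/(r*e)].

Genetic covariances between traits reuse the same expected-mean-square logic
on cross-products (via the polarisation identity), matching a MANOVA
cross-product analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class VarianceComponents:
    s2g: float
    s2ge: float
    s2: float
    r: int                       # replicates
    e: int                       # environments
    truncated: bool              # any negative estimate floored at zero
    anova_table: pd.DataFrame | None = None


@dataclass
class HeritabilityEstimate:
    h2: float
    truncated: bool
    components: VarianceComponents


def _pivot_balanced(pheno: pd.DataFrame) -> np.ndarray:
    """(lines x envs x reps) array; raises unless the design is balanced."""
    lines = pd.unique(pheno["line"])
    envs = pd.unique(pheno["environment"])
    reps = pd.unique(pheno["replicate"])
    expected = len(lines) * len(envs) * len(reps)
    if len(pheno) != expected or pheno.duplicated(["line", "environment", "replicate"]).any():
        raise ValueError(
            "unbalanced design: every line x environment x replicate cell must "
            "be observed exactly once (rebalance or analyse line means)")
    wide = pheno.set_index(["line", "environment", "replicate"])["value"]
    arr = np.empty((len(lines), len(envs), len(reps)))
    for j, env in enumerate(envs):
        for k, rep in enumerate(reps):
            arr[:, j, k] = wide.loc[(lines, env, rep)].to_numpy()
    return arr


def _sums_of_squares(y: np.ndarray) -> dict:
    g, e, r = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_e = y.mean(axis=(0, 2))
    m_ge = y.mean(axis=2)
    m_er = y.mean(axis=0)
    ss = {
        "genotype": e * r * float(np.sum((m_g - grand) ** 2)),
        "environment": g * r * float(np.sum((m_e - grand) ** 2)),
        "rep_in_env": g * float(np.sum((m_er - m_e[:, None]) ** 2)),
        "gxe": r * float(np.sum((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2)),
        "error": float(np.sum((y - m_ge[:, :, None] - m_er[None, :, :] + m_e[None, :, None]) ** 2)),
    }
    df = {
        "genotype": g - 1,
        "environment": e - 1,
        "rep_in_env": e * (r - 1),
        "gxe": (g - 1) * (e - 1),
        "error": e * (g - 1) * (r - 1),
    }
    return {"ss": ss, "df": df, "shape": (g, e, r)}


def anova_components(pheno: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments variance components for one trait.

    ``pheno`` is tidy (line, environment, replicate, value), balanced, with
    at least two replicates (one replicate leaves s2ge and s2 confounded).
    Negative solutions are truncated at zero and flagged.
    """
    y = _pivot_balanced(pheno)
    g, e, r = y.shape
    if r < 2:
        raise ValueError("need >=2 replicates to separate s2ge from error")
    if e < 2:
        raise ValueError("need >=2 environments to estimate s2ge")
    d = _sums_of_squares(y)
    ms = {k: d["ss"][k] / d["df"][k] if d["df"][k] > 0 else 0.0 for k in d["ss"]}
    s2 = ms["error"]
    s2ge = (ms["gxe"] - ms["error"]) / r
    s2g = (ms["genotype"] - ms["gxe"]) / (r * e)
    truncated = s2ge < 0 or s2g < 0
    s2g, s2ge = max(s2g, 0.0), max(s2ge, 0.0)
    # environment tested against replication within environment
    f_env = ms["environment"] / ms["rep_in_env"] if ms["rep_in_env"] > 0 else np.inf
    p_env = float(stats.f.sf(f_env, d["df"]["environment"], d["df"]["rep_in_env"]))
    tbl = pd.DataFrame({
        "source": list(d["ss"]),
        "df": [d["df"][k] for k in d["ss"]],
        "ss": [d["ss"][k] for k in d["ss"]],
        "ms": [ms[k] for k in d["ss"]],
    })
    tbl.attrs["f_environment"] = f_env
    tbl.attrs["p_environment"] = p_env
    return VarianceComponents(s2g, s2ge, s2, r, e, truncated, tbl)


def heritability(vc: VarianceComponents) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability from variance components."""
    if vc.r < 1 or vc.e < 1:
        raise ValueError("r and e must be >= 1")
    denom = vc.s2g + vc.s2ge / vc.e + vc.s2 / (vc.r * vc.e)
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    h2 = vc.s2g / denom
    truncated = not (0.0 <= h2 <= 1.0)
    return HeritabilityEstimate(min(max(h2, 0.0), 1.0), truncated or vc.truncated, vc)


# ---------------------------------------------------------------------------
# correlations

@dataclass
class CorrelationResult:
    r_phenotypic: float
    p_phenotypic: float
    r_genetic: float | None
    cov_genetic: float
    flagged: bool                # rG undefined or outside [-1, 1]


def _genetic_cov(pheno_x: pd.DataFrame, pheno_y: pd.DataFrame) -> float:
    """Genotypic covariance via the polarisation identity on the genotype
    mean squares of x, y and x + y."""
    key = ["line", "environment", "replicate"]
    merged = pheno_x.merge(pheno_y, on=key, suffixes=("_x", "_y"))
    if len(merged) != len(pheno_x):
        raise ValueError("traits measured on different designs")

    def s2g_of(values):
        df = merged[key].copy()
        df["value"] = values
        return _raw_s2g(df)

    sx = s2g_of(merged["value_x"].to_numpy())
    sy = s2g_of(merged["value_y"].to_numpy())
    sxy = s2g_of(merged["value_x"].to_numpy() + merged["value_y"].to_numpy())
    return (sxy - sx - sy) / 2.0


def _raw_s2g(pheno: pd.DataFrame) -> float:
    """s2g without truncation (needed so covariances can be negative)."""
    y = _pivot_balanced(pheno)
    g, e, r = y.shape
    d = _sums_of_squares(y)
    ms_g = d["ss"]["genotype"] / d["df"]["genotype"]
    ms_ge = d["ss"]["gxe"] / d["df"]["gxe"]
    return (ms_g - ms_ge) / (r * e)


def correlations(pheno: pd.DataFrame, trait_x: str, trait_y: str) -> CorrelationResult:
    """Phenotypic (Pearson on line means) and genetic correlation
    rG = Cov_g(x, y) / sqrt(s2g_x * s2g_y) between two traits."""
    px = pheno[pheno["trait"] == trait_x]
    py = pheno[pheno["trait"] == trait_y]
    if px.empty or py.empty:
        raise ValueError("trait not found in phenotype table")
    mx = px.groupby("line")["value"].mean()
    my = py.groupby("line")["value"].mean()
    common = mx.index.intersection(my.index)
    r_p, p_p = stats.pearsonr(mx.loc[common], my.loc[common])
    sx = _raw_s2g(px)
    sy = _raw_s2g(py)
    cov = _genetic_cov(px, py)
    if sx <= 0 or sy <= 0:
        warnings.warn("non-positive genetic variance; rG undefined")
        return CorrelationResult(float(r_p), float(p_p), None, cov, True)
    rg = cov / np.sqrt(sx * sy)
    return CorrelationResult(float(r_p), float(p_p), float(rg), cov, abs(rg) > 1)


def platform_agreement(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between paired measurements of the same samples
    on two platforms."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired measurements must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
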