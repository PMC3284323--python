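"""Founder-strain phenotype statistics.

Replicated measurements on the inbred founder strains support one-way
random-effects analyses: ANOVA for strain differences, the intraclass
correlation r1 = (MSB - MSW) / (MSB + (n - 1) MSW) as broad-sense
heritability, and the coefficient of genetic determination
g2 = (MSB - MSW) / (MSB + (2n - 1) MSW), which discounts the doubling of
additive genetic variance among fully inbred strains.  Unbalanced designs
use the harmonic-mean replicate count.  Count-like hematology traits (PLT,
WBC, LY, MO, NE) are log-transformed before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

#: Traits transformed as log(x + 1) before analysis.
LOG_TRAITS = frozenset({"PLT", "WBC", "LY", "MO", "NE"})

#: Traits carried through I/O but excluded from mapping by default
#: (counts too low to be informative).
NON_MAPPING_TRAITS = frozenset({"EO", "BA"})


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    ms_between: float
    ms_within: float
    sigma2_g: float  # between-strain variance component
    sigma2_e: float  # within-strain variance component
    n_harmonic: float
    df_between: int
    df_within: int


@dataclass
class HeritabilityEstimate:
    r1: float
    g2: float
    ms_between: float
    ms_within: float
    n_per_strain: float
    truncated: bool = False
    degenerate: bool = False


def transform(values: np.ndarray, trait: str, log_traits=LOG_TRAITS) -> np.ndarray:
    """Pre-analysis transform: natural log(x + 1) for listed count traits,
    identity otherwise."""
    values = np.asarray(values, dtype=float)
    if trait in log_traits:
        if (values < 0).any():
            raise ValueError(f"negative values cannot be log-transformed ({trait})")
        return np.log1p(values)
    return values


def inverse_transform(values: np.ndarray, trait: str, log_traits=LOG_TRAITS) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if trait in log_traits:
        return np.expm1(values)
    return values


def _group_arrays(samples: dict[str, np.ndarray]) -> list[np.ndarray]:
    return [np.asarray(v, dtype=float) for v in samples.values()]


def _mean_squares(groups: list[np.ndarray]):
    sizes = np.array([g.size for g in groups], dtype=float)
    a = len(groups)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (a - 1)
    msw = ssw / (N - a) if N > a else 0.0
    n_h = a / (1.0 / sizes).sum()  # harmonic mean replicates per strain
    return msb, msw, n_h, a - 1, int(N - a)


def strain_anova(samples: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA across strains with random-effects variance components.

    ``samples`` maps strain label -> replicate values.  Components come
    from the expected mean squares, sigma2_g = (MSB - MSW) / n with n the
    harmonic-mean group size; a negative estimate is truncated at 0.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 strains")
    groups = _group_arrays(samples)
    if any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 replicates per strain for variance components")
    msb, msw, n_h, dfb, dfw = _mean_squares(groups)
    f_stat, p_value = stats.f_oneway(*groups)
    sigma2_g = max((msb - msw) / n_h, 0.0)
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        ms_between=msb,
        ms_within=msw,
        sigma2_g=sigma2_g,
        sigma2_e=msw,
        n_harmonic=n_h,
        df_between=dfb,
        df_within=dfw,
    )


def heritability(samples: dict[str, np.ndarray]) -> HeritabilityEstimate:
    """Strain-based heritability: intraclass correlation r1 and the
    coefficient of genetic determination g2 (see module docstring).

    Negative component estimates truncate both to 0; MSW = 0 is the
    degenerate perfectly-heritable case (r1 = g2 = 1, flagged).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 strains")
    groups = _group_arrays(samples)
    if any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 replicates per strain")
    msb, msw, n_h, *_ = _mean_squares(groups)
    if msw == 0.0:
        return HeritabilityEstimate(
            r1=1.0, g2=1.0, ms_between=msb, ms_within=msw,
            n_per_strain=n_h, degenerate=True,
        )
    r1 = (msb - msw) / (msb + (n_h - 1.0) * msw)
    g2 = (msb - msw) / (msb + (2.0 * n_h - 1.0) * msw)
    truncated = r1 < 0
    r1 = float(min(max(r1, 0.0), 1.0))
    g2 = float(min(max(g2, 0.0), 1.0))
    return HeritabilityEstimate(
        r1=r1, g2=g2, ms_between=msb, ms_within=msw,
        n_per_strain=n_h, truncated=truncated,
    )


def variance_explained(genotype_class: np.ndarray, trait: np.ndarray) -> float:
    """R-squared of a trait regressed on genotype-class indicators.

    The fraction of phenotypic variance attributable to a locus genotype
    (e.g. the s/s vs s/d vs d/d classes at a biallelic QTL).
    """
    classes = np.asarray(genotype_class)
    y = np.asarray(trait, dtype=float)
    if classes.size != y.size:
        raise ValueError("genotype and trait lengths differ")
    labels = pd.unique(classes)
    if len(labels) < 2:
        raise ValueError("variance explained undefined for a single class")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    ssw = 0.0
    for lab in labels:
        sub = y[classes == lab]
        ssw += float(((sub - sub.mean()) ** 2).sum())
    return 1.0 - ssw / sst


def expression_model(
    records: pd.DataFrame,
    interaction: bool = False,
    trait_col: str = "trait",
    expression_col: str = "delta_ct",
    genotype_col: str = "genotype",
):
    """Linear model of a trait on gene expression (delta-Ct) and genotype.

    ``records`` needs columns for the trait (e.g. MCV in fL), the delta-Ct
    expression measure (target Ct minus reference Ct; lower = more
    expressed, so plots conventionally use -delta-Ct), and a genotype class
    label.  With ``interaction`` the expression x genotype term is added.
    Returns the fitted statsmodels results object (coefficient table,
    p-values via ``.summary()``).

    A single genotype class drops the genotype term with a warning;
    expression perfectly collinear with genotype is flagged.
    """
    df = records.copy()
    for col in (trait_col, expression_col, genotype_col):
        if col not in df.columns:
            raise ValueError(f"records missing column {col!r}")
    if not np.isfinite(df[expression_col].to_numpy(dtype=float)).all():
        raise ValueError("delta_ct values must be finite")
    n_classes = df[genotype_col].nunique()
    if n_classes < 2:
        warnings.warn("single genotype class; genotype term dropped", stacklevel=2)
        formula = f"{trait_col} ~ {expression_col}"
    elif interaction:
        formula = f"{trait_col} ~ {expression_col} * C({genotype_col})"
    else:
        formula = f"{trait_col} ~ {expression_col} + C({genotype_col})"
    model = smf.ols(formula, data=df)
    fit = model.fit()
    if n_classes >= 2:
        exog = model.exog
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            warnings.warn("expression collinear with genotype", stacklevel=2)
    return fit


def simulate_strain_samples(
    strain_means: dict[str, float],
    sigma_within: float,
    n_replicates: int = 8,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Replicate founder-strain phenotypes around given strain means
    (convenience generator for strain-level analyses)."""
    rng = np.random.default_rng(seed)
    return {
        s: rng.normal(mu, sigma_within, size=n_replicates)
        for s, mu in strain_means.items()
    }
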