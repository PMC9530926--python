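"""Mixed-effects association of audiological outcomes with microRNA levels.

Band levels measured on the same subject are repeated measures, so the
default model for one (outcome, microRNA) pair is a single linear mixed
model over all bands with a subject random intercept, fixed band effects
and a band x microRNA interaction; the per-band interaction slopes are the
reported beta coefficients (dB per unit of normalized expression), REML
fitted.  A per-band fixed-effects (OLS) variant is available behind a flag.
An optional DNA-repair genotype factor (hOGG1) can be added to the fixed
effects, emitting one coefficient per variant level.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["BetaReport", "stack_long", "fit_band_models", "fit_genotype_model"]


@dataclass
class BetaReport:
    outcome: str  # AHL | DP
    band: str
    term: str
    beta: float
    se: float
    p: float
    stars: str
    diagnostic: str = ""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def stack_long(
    outcome: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Wide (subject x band) outcome table to long form with covariates.

    Output columns: subject, band (categorical label), level, plus one
    column per covariate (constant within subject).
    """
    long = outcome.reset_index().melt(
        id_vars=outcome.index.name or "index", var_name="band", value_name="level"
    )
    long = long.rename(columns={outcome.index.name or "index": "subject"})
    if long.duplicated(["subject", "band"]).any():
        raise ValueError("duplicate subject x band rows")
    if covariates is not None:
        long = long.merge(
            covariates.reset_index().rename(
                columns={covariates.index.name or "index": "subject"}
            ),
            on="subject",
            how="left",
        )
    return long


def _sanitize(name: str) -> str:
    return re.sub(r"\W", "_", name)


def _reports_from_params(
    params: pd.Series, bse: pd.Series, pvals: pd.Series,
    outcome_label: str, mirna: str, diagnostic: str,
) -> list[BetaReport]:
    reports = []
    for term in params.index:
        m = re.match(r"C\(band\)\[(?:T\.)?(.+?)\]:x_mirna$", term)
        if m:
            band, label = m.group(1), mirna
        elif term.startswith("C(genotype"):
            lvl = re.search(r"\[(?:T\.)?(.+?)\]$", term)
            band, label = "all", f"hOGG1{lvl.group(1)}" if lvl else term
        elif term == "x_mirna":
            band, label = "all", mirna
        else:
            continue
        p = float(pvals[term])
        reports.append(
            BetaReport(
                outcome=outcome_label,
                band=band,
                term=label,
                beta=float(params[term]),
                se=float(bse[term]),
                p=p,
                stars=significance_stars(p),
                diagnostic=diagnostic,
            )
        )
    return reports


def _fit(
    data: pd.DataFrame,
    fixed: str,
    outcome_label: str,
    mirna: str,
    use_mixed: bool,
) -> list[BetaReport]:
    diagnostic = ""
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(fixed, data, groups=data["subject"]).fit(reml=True)
            if not np.all(np.isfinite(fit.bse[fit.fe_params.index])):
                raise ValueError("non-finite standard errors")
            if not fit.converged:
                diagnostic = "mixed model did not converge; estimates reported"
            return _reports_from_params(
                fit.fe_params,
                fit.bse[fit.fe_params.index],
                fit.pvalues[fit.fe_params.index],
                outcome_label, mirna, diagnostic,
            )
        except Exception as exc:  # singular/degenerate variance structure
            diagnostic = f"mixed fit failed ({type(exc).__name__}); OLS fallback"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(fixed, data).fit()
    return _reports_from_params(
        fit.params, fit.bse, fit.pvalues, outcome_label, mirna, diagnostic
    )


def fit_band_models(
    data: pd.DataFrame,
    mirna: str,
    outcome_label: str = "AHL",
    per_band: bool = False,
) -> list[BetaReport]:
    """Per-band microRNA slopes for one outcome.

    ``data`` is a long table from :func:`stack_long` with a column named by
    ``mirna``.  Default: one REML mixed model, subject random intercept,
    ``level ~ 0 + band + band:mirna``; per-band betas are the interaction
    slopes.  With ``per_band=True``, an independent OLS ``level ~ mirna``
    is fitted within each band instead.
    """
    bands = data["band"].unique()
    if len(bands) < 2 and not per_band:
        raise ValueError("need at least 2 bands for the repeated-measures model")
    if data["subject"].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    if mirna not in data.columns:
        raise KeyError(f"covariate column {mirna!r} not found")
    if np.ptp(data[mirna].to_numpy(dtype=float)) == 0:
        raise ValueError(f"covariate {mirna!r} is constant; slope inestimable")

    df = data.copy()
    df["x_mirna"] = df[mirna].astype(float)
    if per_band:
        reports: list[BetaReport] = []
        for band in bands:
            sub = df[df["band"] == band]
            fit = smf.ols("level ~ x_mirna", sub).fit()
            p = float(fit.pvalues["x_mirna"])
            reports.append(
                BetaReport(
                    outcome=outcome_label, band=str(band), term=mirna,
                    beta=float(fit.params["x_mirna"]), se=float(fit.bse["x_mirna"]),
                    p=p, stars=significance_stars(p),
                )
            )
        return reports
    return _fit(
        df, "level ~ 0 + C(band) + C(band):x_mirna", outcome_label, mirna, use_mixed=True
    )


def fit_genotype_model(
    data: pd.DataFrame,
    mirna: str,
    genotype: str = "hOGG1",
    reference: str = "het",
    pool: dict[str, str] | None = None,
    outcome_label: str = "DP",
) -> list[BetaReport]:
    """Mixed model with an added genotype fixed factor.

    ``pool`` optionally maps raw variant -> pooled level (e.g.
    ``{"mut": "mut_het", "het": "mut_het", "wt": "wt"}`` for the two-level
    hOGG1 grouping); by default each variant is its own level and the
    reference level's coefficient is absorbed, so the emitted terms are
    labelled like ``hOGG1mut`` / ``hOGG1wt``.
    """
    if genotype not in data.columns:
        raise KeyError(f"genotype column {genotype!r} not found")
    df = data.copy()
    df["x_mirna"] = df[mirna].astype(float)
    df["genotype"] = df[genotype].astype(str)
    if pool:
        df["genotype"] = df["genotype"].map(lambda g: pool.get(g, g))
        reference = pool.get(reference, reference)
    counts = df.groupby("genotype")["subject"].nunique()
    empty = [g for g in counts.index if counts[g] == 0]
    if len(counts) < 2:
        raise ValueError(
            f"genotype factor needs at least 2 populated levels, found {list(counts.index)}"
        )
    if reference not in set(df["genotype"]):
        raise ValueError(f"reference level {reference!r} has no subjects")
    if empty:
        raise ValueError(f"genotype level(s) with no subjects: {empty}")
    fixed = (
        "level ~ 0 + C(band) + C(band):x_mirna "
        f"+ C(genotype, Treatment(reference={reference!r}))"
    )
    return _fit(df, fixed, outcome_label, mirna, use_mixed=True)


def beta_frame(reports: list[BetaReport]) -> pd.DataFrame:
    """Flatten reports into the tab-separated beta-table layout."""
    return pd.DataFrame(
        {
            "outcome": [r.outcome for r in reports],
            "band": [r.band for r in reports],
            "term": [r.term for r in reports],
            "beta": [r.beta for r in reports],
            "se": [r.se for r in reports],
            "p": [r.p for r in reports],
            "stars": [r.stars for r in reports],
            "diagnostic": [r.diagnostic for r in reports],
        }
    )
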