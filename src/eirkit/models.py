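"""Mixed-effects logistic regression with nested random intercepts.

Outcomes (nonassigned visit, any-MOV, vaccine-specific MOV, dropout) are
modelled as Bernoulli with fixed effects for patient/facility covariates
and nested random intercepts for region, district and facility, encoded
by concatenated keys (region, region:district, region:district:facility)
so nesting holds regardless of ID reuse across regions.

Fitting is delegated to an established mixed-model routine rather than
implemented here.  The default backend is lme4's ``glmer`` (Laplace
maximum likelihood, run through ``Rscript``), whose fixed-effect
estimates coincide with plain logistic regression when the variance
components hit the zero boundary and whose Wald standard errors are
well calibrated for cluster-level covariates.  When R is unavailable
the backend falls back to statsmodels' Bayesian mixed GLM (Laplace
posterior-mode fit; a variational fit is also exposed, which estimates
variance components well but underestimates fixed-effect SDs for
cluster-level covariates).  Odds ratios are exponentiated fixed-effect
estimates with Wald 95% intervals.  Singular or failed fits fall back
to fewer nesting levels and finally to a plain logistic regression,
with the fallback recorded in the result — a fit never returns silent
estimates after non-convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

NESTING_LEVELS = ("region", "district", "facility")


@dataclass
class Covariate:
    """One fixed-effect term: continuous, or categorical with an explicit
    reference level."""

    name: str
    kind: str = "categorical"  # or "continuous"
    reference: Optional[str] = None
    log_transform: bool = False


@dataclass
class ModelSpec:
    outcome: str
    fixed_effects: list[Covariate]
    random_intercepts: tuple[str, ...] = NESTING_LEVELS
    adjusted: bool = True

    def __post_init__(self) -> None:
        if not self.adjusted and len(self.fixed_effects) != 1:
            raise ValueError("unadjusted spec takes exactly one fixed effect")
        if tuple(self.random_intercepts) != NESTING_LEVELS[
                :len(self.random_intercepts)]:
            raise ValueError("random intercepts must be a prefix of "
                             f"{NESTING_LEVELS} (nesting order is fixed)")


@dataclass
class ModelResult:
    """Per-level odds ratios with 95% CIs, plus fit diagnostics."""

    table: pd.DataFrame
    method: str                      # "mixed_vb" or "logit"
    converged: bool
    nesting_used: tuple[str, ...]
    fallback: Optional[str] = None
    vc_sd: dict = field(default_factory=dict)


def build_design(analysis_table: pd.DataFrame, spec: ModelSpec
                 ) -> pd.DataFrame:
    """Model-ready table: 0/1 outcome, typed covariates and the three
    concatenated cluster keys.  Categorical covariates become ordered
    categoricals with the reference level first; continuous covariates
    marked ``log_transform`` are log-transformed here."""
    df = analysis_table.copy()
    df["_y"] = pd.to_numeric(df[spec.outcome]).astype(int)
    if not df["_y"].isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    for cov in spec.fixed_effects:
        col = df[cov.name]
        if cov.kind == "categorical":
            levels = sorted(map(str, col.dropna().unique()))
            ref = cov.reference if cov.reference is not None else levels[0]
            cov.reference = ref
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent for "
                                 f"{cov.name}")
            ordered = [ref] + [l for l in levels if l != ref]
            empties = [l for l in levels if (col == l).sum() == 0]
            if empties:
                warnings.warn(f"{cov.name}: empty level(s) {empties} retained")
            df[cov.name] = pd.Categorical(col.astype(str), categories=ordered)
        else:
            vals = pd.to_numeric(col)
            if cov.log_transform:
                vals = np.log(vals)
            df[cov.name] = vals
    df = df.dropna(subset=["_y"] + [c.name for c in spec.fixed_effects])
    df["_region"] = df["region"].astype(str)
    df["_district"] = df["_region"] + ":" + df["district"].astype(str)
    df["_facility"] = df["_district"] + ":" + df["facility_id"].astype(str)
    return df


def _formula(spec: ModelSpec) -> str:
    terms = []
    for cov in spec.fixed_effects:
        if cov.kind == "categorical":
            terms.append(f"C({cov.name})")
        else:
            terms.append(cov.name)
    return "_y ~ " + " + ".join(terms)


def _result_table(spec: ModelSpec, names: Sequence[str], mean: np.ndarray,
                  sd: np.ndarray) -> pd.DataFrame:
    rows = []
    by_name = dict(zip(names, zip(mean, sd)))
    for cov in spec.fixed_effects:
        if cov.kind == "categorical":
            # patsy names look like C(name)[T.level]; reference row first
            rows.append({"term": cov.name, "level": cov.reference,
                         "odds_ratio": 1.0, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan,
                         "is_reference": True})
            prefix = f"C({cov.name})[T."
            for nm in names:
                if nm.startswith(prefix):
                    m, s = by_name[nm]
                    rows.append(_or_row(cov.name, nm[len(prefix):-1], m, s))
        else:
            m, s = by_name[cov.name]
            rows.append(_or_row(cov.name, "", m, s))
    return pd.DataFrame(rows)


def _or_row(term: str, level: str, m: float, s: float) -> dict:
    z = m / s if s > 0 else np.inf
    return {"term": term, "level": level, "odds_ratio": float(np.exp(m)),
            "ci_low": float(np.exp(m - 1.96 * s)),
            "ci_high": float(np.exp(m + 1.96 * s)),
            "p_value": float(2 * stats.norm.sf(abs(z))),
            "is_reference": False}


def _fit_plain_logit(design: pd.DataFrame, spec: ModelSpec,
                     fallback: Optional[str]) -> ModelResult:
    import patsy
    y, X = patsy.dmatrices(_formula(spec), design, return_type="dataframe")
    model = sm.Logit(np.asarray(y).ravel(), X)
    res = model.fit(disp=0, maxiter=200)
    names = list(X.columns)
    mean = np.asarray(res.params)
    sd = np.asarray(res.bse)
    keep = [i for i, nm in enumerate(names) if nm != "Intercept"]
    table = _result_table(spec, [names[i] for i in keep],
                          mean[keep], sd[keep])
    return ModelResult(table=table, method="logit",
                       converged=bool(res.mle_retvals.get("converged", True)),
                       nesting_used=(), fallback=fallback)


class FitError(RuntimeError):
    """Raised when every fitting strategy fails."""


def _have_rscript() -> bool:
    import shutil
    return shutil.which("Rscript") is not None


_GLMER_SCRIPT = """\
suppressMessages(library(lme4))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
f <- as.formula(readLines(args[2])[1])
m <- glmer(f, data = d, family = binomial, nAGQ = 1,
           control = glmerControl(calc.derivs = FALSE))
fe <- fixef(m)
se <- sqrt(diag(as.matrix(vcov(m))))
vc <- as.data.frame(lme4::VarCorr(m))
write.csv(data.frame(term = names(fe), est = fe, se = se),
          args[3], row.names = FALSE)
write.csv(vc[, c("grp", "sdcor")], args[4], row.names = FALSE)
"""


def _fit_lme4(design: pd.DataFrame, spec: ModelSpec,
              levels: list[str]) -> tuple[list[str], np.ndarray, np.ndarray,
                                          dict]:
    """One glmer fit through Rscript; returns (patsy term names, estimates,
    SEs, variance-component SDs).  Dummy encoding is done here with patsy
    so reference levels are identical across backends."""
    import subprocess
    import tempfile

    import patsy
    y, X = patsy.dmatrices(_formula(spec), design, return_type="dataframe")
    names = [nm for nm in X.columns if nm != "Intercept"]
    d = pd.DataFrame({"y": np.asarray(y).ravel().astype(int)})
    safe = {}
    for i, nm in enumerate(names):
        safe[f"x{i}"] = nm
        d[f"x{i}"] = X[nm].to_numpy()
    for lev in levels:
        d[f"g_{lev}"] = design[f"_{lev}"].to_numpy()
    fixed = " + ".join(safe) if safe else "1"
    rand = " + ".join(f"(1|g_{lev})" for lev in levels)
    formula = f"y ~ {fixed} + {rand}"
    with tempfile.TemporaryDirectory() as tmp:
        data_path = f"{tmp}/design.csv"
        d.to_csv(data_path, index=False)
        with open(f"{tmp}/formula.txt", "w") as fh:
            fh.write(formula + "\n")
        with open(f"{tmp}/fit.R", "w") as fh:
            fh.write(_GLMER_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", f"{tmp}/fit.R", data_path,
             f"{tmp}/formula.txt", f"{tmp}/fe.csv", f"{tmp}/vc.csv"],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise FitError(f"glmer failed: {proc.stderr.strip()[-300:]}")
        fe = pd.read_csv(f"{tmp}/fe.csv").set_index("term")
        vc = pd.read_csv(f"{tmp}/vc.csv")
    est = np.array([fe.loc[f"x{i}", "est"] for i in range(len(names))])
    se = np.array([fe.loc[f"x{i}", "se"] for i in range(len(names))])
    vc_sd = {lev: float(vc.loc[vc["grp"] == f"g_{lev}", "sdcor"].iloc[0])
             for lev in levels if (vc["grp"] == f"g_{lev}").any()}
    return names, est, se, vc_sd


def _fit_statsmodels(design: pd.DataFrame, spec: ModelSpec,
                     levels: list[str], fit_method: str
                     ) -> tuple[list[str], np.ndarray, np.ndarray, dict]:
    vc = {lev: f"0 + C(_{lev})" for lev in levels}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(_formula(spec), vc, design)
        res = model.fit_vb() if fit_method == "vb" else model.fit_map()
    if not np.all(np.isfinite(res.fe_mean)) or not np.all(
            np.isfinite(res.fe_sd)) or np.any(res.fe_sd <= 0):
        raise FitError("non-finite fixed-effect estimates")
    names = list(model.fep_names)
    keep = [i for i, nm in enumerate(names) if nm != "Intercept"]
    vc_sd = {lev: float(np.exp(m)) for lev, m in zip(levels, res.vcp_mean)}
    return ([names[i] for i in keep], res.fe_mean[keep], res.fe_sd[keep],
            vc_sd)


def fit_mixed_logit(design: pd.DataFrame, spec: ModelSpec,
                    backend: str = "auto") -> ModelResult:
    """Fit the mixed-effects logistic model, falling back to fewer
    nesting levels (then plain logit) on degenerate or failed fits.

    ``backend``: ``"auto"`` (lme4 when Rscript is on PATH, else the
    statsmodels Laplace fit), ``"lme4"``, ``"map"`` or ``"vb"``.
    """
    if backend == "auto":
        backend = "lme4" if _have_rscript() else "map"
    levels = list(spec.random_intercepts)
    fallback = None
    while levels:
        n_clusters = min(design[f"_{lev}"].nunique() for lev in levels)
        if n_clusters < 2:
            fallback = "single cluster at some nesting level"
            break
        try:
            if backend == "lme4":
                names, est, se, vc_sd = _fit_lme4(design, spec, levels)
            else:
                names, est, se, vc_sd = _fit_statsmodels(design, spec,
                                                         levels, backend)
            table = _result_table(spec, names, est, se)
            method = "lme4" if backend == "lme4" else f"mixed_{backend}"
            return ModelResult(table=table, method=method, converged=True,
                               nesting_used=tuple(levels), fallback=fallback,
                               vc_sd=vc_sd)
        except (FitError, np.linalg.LinAlgError, ValueError, OSError) as exc:
            fallback = f"dropped level {levels[-1]!r} after: {exc}"
            levels = levels[:-1]
    return _fit_plain_logit(design, spec, fallback or "no usable nesting")


PCT_P_FLOOR = 0.001


def format_or(value: float, lo: float, hi: float) -> str:
    return f"{value:.2f} ({lo:.2f}-{hi:.2f})"


def format_p(p: float) -> str:
    if pd.isna(p):
        return "N/A"
    if p < PCT_P_FLOOR:
        return "<.001"
    return f"{p:.2f}".lstrip("0") if p >= 0.005 else f"{p:.3f}".lstrip("0")


def result_table(results: Mapping[str, ModelResult]) -> pd.DataFrame:
    """Side-by-side formatted OR table, one column pair per fitted model
    (e.g. unadjusted and adjusted).  Reference rows render "Reference"."""
    frames = []
    for label, res in results.items():
        t = res.table.copy()
        t[f"{label}_OR"] = [
            "Reference" if r.is_reference
            else format_or(r.odds_ratio, r.ci_low, r.ci_high)
            for r in t.itertuples()]
        t[f"{label}_p"] = ["N/A" if r.is_reference else format_p(r.p_value)
                           for r in t.itertuples()]
        frames.append(t.set_index(["term", "level"])[
            [f"{label}_OR", f"{label}_p"]])
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.join(f, how="outer")
    return merged.fillna("N/A").reset_index()
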