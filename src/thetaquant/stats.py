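"""Linear mixed-effects models for epoch peak-range tables.

Group comparisons of the peak-range statistic use linear mixed-effects
models with nested random intercepts (e.g. species/subject/session) to
respect the hierarchical sampling of epochs within sessions within
animals. Models are fitted by REML via :mod:`statsmodels` ``MixedLM``;
the nesting is expressed with variance components inside the outermost
grouping factor. Fixed-effect p-values use the large-sample Wald normal
approximation (``wald-z``), which is indistinguishable from
finite-sample degree-of-freedom corrections at the epoch counts these
tables carry; the method is always recorded in the result.

A registry (``eq1`` … ``eq9``) exposes the standard model set: the
cross-species locomotion interaction model with its per-species refits,
the atropine x locomotor-state model with per-state refits, and the
trial-epoch x channel model with per-channel refits. Tukey-adjusted
pairwise contrasts are available for factors with three or more levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = ["LMMSpec", "LMMResult", "fit_lmm", "tukey_contrasts",
           "bonferroni_alpha", "MODEL_REGISTRY", "fit_registry_model"]


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Bonferroni-corrected per-test threshold ``family_alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


@dataclass
class LMMSpec:
    """Declarative mixed-model specification.

    ``fixed`` is the fixed-effects part of the formula (patsy syntax,
    without the response); ``groups`` is the nesting path of random
    intercepts from outermost to innermost, e.g.
    ``["Species", "ID", "Session"]`` for ``(1|Species/ID/Session)``.
    ``references`` fixes the reference level of categorical fixed
    effects; ``subset`` optionally restricts rows before fitting.
    """

    fixed: str
    groups: Sequence[str]
    response: str = "peak_range"
    references: Dict[str, str] = field(default_factory=dict)
    subset: Optional[Tuple[str, object]] = None

    def formula(self) -> str:
        fixed = self.fixed
        for col, ref in self.references.items():
            fixed = fixed.replace(col, f"C({col}, Treatment('{ref}'))")
        return f"{self.response} ~ {fixed}"


@dataclass
class LMMResult:
    """Fixed effects (beta, SE, t, p), variance components and fit metadata."""

    fixed_effects: pd.DataFrame       # index: term; columns: beta, se, t, p
    random_variances: Dict[str, float]
    n_obs: int
    converged: bool
    df_method: str
    spec: LMMSpec
    _model_result: object = None

    def coef(self, term_contains: str) -> pd.Series:
        hits = self.fixed_effects[self.fixed_effects.index.str.contains(term_contains, regex=False)]
        if len(hits) != 1:
            raise KeyError(f"{term_contains!r} matches {len(hits)} fixed-effect terms")
        return hits.iloc[0]


def _prepare(table: pd.DataFrame, spec: LMMSpec) -> Tuple[pd.DataFrame, Optional[str], Dict[str, str]]:
    df = table.copy()
    if spec.subset is not None:
        col, val = spec.subset
        df = df[df[col] == val].copy()
    for col in spec.groups:
        if col not in df.columns:
            raise ValueError(f"grouping column {col!r} missing from table")
        if df[col].nunique() < 2:
            raise ValueError(f"grouping factor {col!r} has a single level; "
                             "a random intercept cannot be estimated")
    groups = spec.groups[0]
    vc: Dict[str, str] = {}
    prev = None
    for depth, col in enumerate(spec.groups[1:], start=1):
        name = f"__nest{depth}"
        parts = [df[c].astype(str) for c in spec.groups[1:depth + 1]]
        combo = parts[0]
        for p in parts[1:]:
            combo = combo + "/" + p
        df[name] = combo
        vc[col] = f"0 + C({name})"
        prev = name
    return df, groups, vc


def fit_lmm(table: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    """REML fit of ``spec`` on an epoch table.

    Nested random intercepts are realised as variance components within
    the outermost grouping factor. Non-convergence is flagged in the
    result, never silently simplified.
    """
    df, groups, vc = _prepare(table, spec)
    if df[spec.response].isna().any():
        df = df.dropna(subset=[spec.response])
    model = smf.mixedlm(spec.formula(), df, groups=df[groups],
                        re_formula="1", vc_formula=vc or None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs", maxiter=10000)
    fe_names = fit.fe_params.index
    beta = fit.fe_params
    se = fit.bse_fe
    t = beta / se
    p = 2.0 * sps.norm.sf(np.abs(t))
    fe = pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p}, index=fe_names)
    rv = {groups: float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else np.nan}
    if vc:
        for name, var in zip(vc.keys(), np.atleast_1d(fit.vcomp)):
            rv[name] = float(var)
    rv["residual"] = float(fit.scale)
    return LMMResult(fixed_effects=fe, random_variances=rv, n_obs=int(fit.nobs),
                     converged=bool(getattr(fit, "converged", True)),
                     df_method="wald-z", spec=spec, _model_result=fit)


def tukey_contrasts(result: LMMResult, factor: str) -> pd.DataFrame:
    """All pairwise contrasts of a categorical fixed effect, Tukey-adjusted.

    Level marginal means are read off the treatment-coded coefficients
    (valid for models where the factor enters without interactions, the
    per-stratum refits of the registry). The studentized-range
    distribution with the residual degrees of freedom supplies the
    adjusted p. For a 2-level factor the model p is passed through with
    a note.
    """
    fit = result._model_result
    fe = result.fixed_effects
    prefix = f"C({factor}"
    terms = [t for t in fe.index if t.startswith(prefix) or t.startswith(factor + "[")]
    if any("]:" in t or ":C(" in t for t in terms):
        raise ValueError(f"{factor} participates in an interaction; "
                         "refit on the relevant stratum before contrasting")
    ref = result.spec.references.get(factor)
    levels = {ref if ref is not None else "(ref)": None}
    for t in terms:
        level = t.split("[T.")[-1].rstrip("]")
        levels[level] = t
    names = list(levels)
    k = len(names)
    cov = fit.cov_params().loc[fe.index, fe.index]
    df_resid = max(result.n_obs - len(fe), 1)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            vec = pd.Series(0.0, index=fe.index)
            if levels[names[i]] is not None:
                vec[levels[names[i]]] = 1.0
            if levels[names[j]] is not None:
                vec[levels[names[j]]] = -1.0
            est = float(vec @ fe["beta"])
            se = float(np.sqrt(vec @ cov @ vec))
            if k == 2:
                term = levels[names[i]] or levels[names[j]]
                rows.append({"contrast": f"{names[i]} - {names[j]}", "estimate": est,
                             "se": se, "p_adj": float(fe.loc[term, "p"]),
                             "note": "2-level factor: model p passed through"})
            else:
                q = np.abs(est) / se * np.sqrt(2.0)
                p_adj = float(sps.studentized_range.sf(q, k, df_resid))
                rows.append({"contrast": f"{names[i]} - {names[j]}", "estimate": est,
                             "se": se, "p_adj": p_adj, "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model registry

_REF = {"MovFlag": "immobile", "DrugFlag": "none", "Species": "rat", "Epoch": "Run"}


def _refs(*cols: str) -> Dict[str, str]:
    return {c: _REF[c] for c in cols}


MODEL_REGISTRY: Dict[str, LMMSpec] = {
    # cross-species locomotion contrast and its per-species refits
    "eq1": LMMSpec(fixed="MovFlag * Species + Chan", groups=["Species", "ID", "Session"],
                   references=_refs("MovFlag", "Species")),
    "eq2": LMMSpec(fixed="MovFlag + Chan", groups=["ID", "Session"],
                   references=_refs("MovFlag"), subset=("Species", "rat")),
    "eq3": LMMSpec(fixed="MovFlag + Chan", groups=["ID", "Session"],
                   references=_refs("MovFlag"), subset=("Species", "ferret")),
    # atropine x locomotor state and per-state refits
    "eq4": LMMSpec(fixed="MovFlag * DrugFlag", groups=["ID", "Chan", "Session"],
                   references=_refs("MovFlag", "DrugFlag")),
    "eq5": LMMSpec(fixed="DrugFlag", groups=["ID", "Chan", "Session"],
                   references=_refs("DrugFlag"), subset=("MovFlag", "moving")),
    "eq6": LMMSpec(fixed="DrugFlag", groups=["ID", "Chan", "Session"],
                   references=_refs("DrugFlag"), subset=("MovFlag", "immobile")),
    # trial-epoch x channel and per-channel refits
    "eq7": LMMSpec(fixed="Epoch * Chan", groups=["ID", "Session"],
                   references=_refs("Epoch")),
    "eq8": LMMSpec(fixed="Epoch", groups=["ID", "Session"],
                   references=_refs("Epoch"), subset=("Chan", "SO")),
    "eq9": LMMSpec(fixed="Epoch", groups=["ID", "Session"],
                   references=_refs("Epoch"), subset=("Chan", "SRSLM")),
}


def fit_registry_model(table: pd.DataFrame, name: str) -> LMMResult:
    """Fit one of the registered models (``eq1`` ... ``eq9``)."""
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}")
    return fit_lmm(table, MODEL_REGISTRY[name])


def split_model_workflow(table: pd.DataFrame, full: str,
                         splits: Sequence[str]) -> Dict[str, LMMResult]:
    """Interaction model followed by per-stratum refits, as one workflow.

    Returns the full-model fit plus every per-stratum refit keyed by
    registry name, so both stages of the protocol are reported together.
    """
    out = {full: fit_registry_model(table, full)}
    for name in splits:
        out[name] = fit_registry_model(table, name)
    return out
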