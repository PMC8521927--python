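"""Meteorological regressor selection for sleep parameters.

The selection procedure is adaptive LASSO (L1 penalty with per-coefficient
weights 1/|OLS estimate|) over the meteorological candidates, with gender and
age-group always included unpenalized, the model on the penalization path
chosen by the Schwarz Bayesian Criterion (SBC), and selected terms pruned to
those significant at p < 0.01 in an unpenalized refit. Selection is wrapped
in bootstrap model averaging: it is repeated on B resamples, each candidate
is scored by its selection frequency, the final model keeps candidates above
a frequency cutoff (70% by default), and the reported coefficient is the
ensemble average of the final model refit to each resample. Ridge- and
elastic-net-based selection are available for robustness comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path, lasso_path

from ._rng import substream

ALPHA = 0.01
DEFAULT_CANDIDATES = ("ta", "humidity", "pressure", "sunset", "sunrise")


class DegenerateDesignError(ValueError):
    """Candidates are perfectly collinear; adaptive weights are undefined."""


@dataclass(frozen=True)
class DesignSpec:
    """Response + penalized candidates + unpenalized adjustment terms."""

    response: str
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    adjustments: tuple[str, ...] = ("age_group", "gender")

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("need at least one candidate regressor")


@dataclass
class SelectedModel:
    terms: list[str]
    coefficients: dict[str, float]   # candidate coefficients, original scale
    sbc: float
    termination: str


@dataclass
class AveragedModel:
    table: pd.DataFrame              # candidate, frequency, ensemble_coef, ensemble_se
    selected: list[str]
    cutoff: float
    replicates: int
    seed: int
    n_skipped: int = 0
    supports: list[frozenset] = field(repr=False, default_factory=list)

    def coefficient(self, candidate: str) -> float:
        row = self.table.set_index("candidate").loc[candidate]
        return float(row["ensemble_coef"])


# ---------------------------------------------------------------------------
# design construction and OLS machinery
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame, design: DesignSpec):
    """(y, Z, X) arrays: response, unpenalized block (with intercept), candidates."""
    if "gender" in data.columns:
        data = data[data["gender"] != "unknown"]
    y = data[design.response].to_numpy(dtype=float)
    blocks = [np.ones((len(data), 1))]
    for adj in design.adjustments:
        if adj in data.columns:
            d = pd.get_dummies(data[adj], drop_first=True, dtype=float)
            blocks.append(d.to_numpy())
    Z = np.hstack(blocks)
    X = data[list(design.candidates)].to_numpy(dtype=float)
    return y, Z, X


def _ols(A: np.ndarray, y: np.ndarray):
    """beta, se, p, rss via least squares (pinv covariance)."""
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    dof = max(len(y) - rank, 1)
    sigma2 = rss / dof
    cov = np.linalg.pinv(A.T @ A) * sigma2
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, p, rss


def _sbc(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + k * np.log(n)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        raise DegenerateDesignError("constant candidate column")
    return (X - mu) / sd, sd


def _prune_support(y, Z, Xs, support: list[int], alpha_p: float) -> tuple[list[int], float, np.ndarray]:
    """Drop refit-insignificant candidates to fixpoint; return support, SBC, betas."""
    support = list(support)
    while True:
        A = np.hstack([Z, Xs[:, support]]) if support else Z
        beta, _, p, rss = _ols(A, y)
        if not support:
            return support, _sbc(rss, len(y), A.shape[1]), np.empty(0)
        cand_p = p[Z.shape[1]:]
        keep = [s for s, pv in zip(support, cand_p) if pv < alpha_p]
        if len(keep) == len(support):
            return support, _sbc(rss, len(y), A.shape[1]), beta[Z.shape[1]:]
        support = keep


# ---------------------------------------------------------------------------
# selectors (array level)
# ---------------------------------------------------------------------------

def _path_supports(coefs: np.ndarray) -> list[list[int]]:
    """Distinct supports along a coefficient path, sparsest first."""
    seen, out = set(), []
    for j in range(coefs.shape[1]):
        s = tuple(np.flatnonzero(np.abs(coefs[:, j]) > 0).tolist())
        if s not in seen:
            seen.add(s)
            out.append(list(s))
    full = tuple(range(coefs.shape[0]))
    if full not in seen:
        out.append(list(full))
    if () not in seen:
        out.insert(0, [])
    return out


def _select_l1(y, Z, X, alpha_p: float, l1_ratio: float = 1.0):
    """Adaptive LASSO (or elastic-net) support via SBC along the path."""
    k = X.shape[1]
    Xs, _ = _standardize(X)
    if np.linalg.matrix_rank(Xs) < k:
        raise DegenerateDesignError("perfectly collinear candidates")
    beta_init, *_ = np.linalg.lstsq(np.hstack([Z, Xs]), y, rcond=None)
    w = np.abs(beta_init[Z.shape[1]:])  # adaptive scale = |OLS estimate|, gamma = 1
    yr = _residualize(y, Z)
    Xr = _residualize(Xs, Z) * w  # x_j * |b_j| <=> penalty weight 1/|b_j|
    if l1_ratio >= 1.0:
        _, coefs, _ = lasso_path(Xr, yr)
    else:
        _, coefs, _ = enet_path(Xr, yr, l1_ratio=l1_ratio)
    best = (np.inf, [])
    for support in _path_supports(coefs):
        A = np.hstack([Z, Xs[:, support]]) if support else Z
        _, _, _, rss = _ols(A, y)
        sbc = _sbc(rss, len(y), A.shape[1])
        if sbc < best[0]:
            best = (sbc, support)
    support, sbc, _ = _prune_support(y, Z, Xs, best[1], alpha_p)
    return support


def _select_ridge(y, Z, X, alpha_p: float):
    """Ridge-style selection: significance of the unpenalized full refit."""
    k = X.shape[1]
    Xs, _ = _standardize(X)
    if np.linalg.matrix_rank(Xs) < k:
        raise DegenerateDesignError("perfectly collinear candidates")
    support, _, _ = _prune_support(y, Z, Xs, list(range(k)), alpha_p)
    return support


_SELECTORS = {
    "adaptive_lasso": lambda y, Z, X, a: _select_l1(y, Z, X, a, l1_ratio=1.0),
    "elastic_net": lambda y, Z, X, a: _select_l1(y, Z, X, a, l1_ratio=0.5),
    "ridge": _select_ridge,
}


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def adaptive_lasso(
    design: DesignSpec,
    data: pd.DataFrame,
    alpha_p: float = ALPHA,
    zero_penalty: bool = False,
    l1_ratio: float = 1.0,
) -> SelectedModel:
    """Single-dataset adaptive-LASSO selection with SBC model choice.

    ``zero_penalty=True`` skips the path and pruning entirely and returns the
    ordinary least-squares fit of all candidates (the unpenalized limit).
    """
    y, Z, X = build_design(data, design)
    if len(y) <= Z.shape[1] + X.shape[1]:
        raise ValueError("need more rows than design columns")
    names = list(design.candidates)
    if zero_penalty:
        A = np.hstack([Z, X])
        beta, _, _, rss = _ols(A, y)
        coefs = dict(zip(names, beta[Z.shape[1]:]))
        return SelectedModel(terms=names, coefficients=coefs,
                             sbc=_sbc(rss, len(y), A.shape[1]), termination="zero_penalty")
    support = _select_l1(y, Z, X, alpha_p, l1_ratio=l1_ratio)
    A = np.hstack([Z, X[:, support]]) if support else Z
    beta, _, _, rss = _ols(A, y)
    coefs = {names[s]: float(b) for s, b in zip(support, beta[Z.shape[1]:])}
    return SelectedModel(
        terms=[names[s] for s in support],
        coefficients=coefs,
        sbc=_sbc(rss, len(y), A.shape[1]),
        termination="sbc_minimum" if support else "all_terms_insignificant",
    )


def bootstrap_model_average(
    design: DesignSpec,
    data: pd.DataFrame,
    B: int = 5000,
    cutoff: float = 70.0,
    seed: int = 0,
    selector: str = "adaptive_lasso",
    alpha_p: float = ALPHA,
    average_all_resamples: bool = True,
) -> AveragedModel:
    """Bootstrap model averaging around a selection rule.

    B record-level resamples (with replacement, resample size = n) are drawn;
    the selector runs on each; candidates selected in at least ``cutoff``
    percent of resamples form the final model, whose coefficients are the
    ensemble average of the final model refit to every resample (or, with
    ``average_all_resamples=False``, only to the resamples that selected the
    candidate).
    """
    if B < 2:
        raise ValueError("need at least two bootstrap replicates")
    if not (0 < cutoff <= 100):
        raise ValueError("cutoff must be in (0, 100]")
    select = _SELECTORS[selector]
    y, Z, X = build_design(data, design)
    names = list(design.candidates)
    n, k = len(y), X.shape[1]
    rng = substream(seed, f"bootstrap:{design.response}:{selector}")

    counts = np.zeros(k)
    supports: list[frozenset] = []
    indices = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            support = select(y[idx], Z[idx], X[idx], alpha_p)
        except DegenerateDesignError:
            skipped += 1
            continue
        counts[support] += 1
        supports.append(frozenset(names[s] for s in support))
        indices.append(idx)
    valid = B - skipped
    if skipped > 0.1 * B:
        raise RuntimeError(f"{skipped}/{B} bootstrap resamples degenerate")

    freq = 100.0 * counts / valid
    final_idx = [j for j in range(k) if freq[j] >= cutoff]

    coef_draws = np.full((valid, k), np.nan)
    for b, idx in enumerate(indices):
        A = np.hstack([Z[idx], X[idx][:, final_idx]]) if final_idx else Z[idx]
        beta, *_ = np.linalg.lstsq(A, y[idx], rcond=None)
        coef_draws[b, final_idx] = beta[Z.shape[1]:]
        if not average_all_resamples:
            sel = supports[b]
            for j in final_idx:
                if names[j] not in sel:
                    coef_draws[b, j] = np.nan

    ens_mean = np.full(k, np.nan)
    ens_se = np.full(k, np.nan)
    for j in final_idx:
        draws = coef_draws[:, j]
        draws = draws[np.isfinite(draws)]
        if draws.size:
            ens_mean[j] = draws.mean()
            ens_se[j] = draws.std(ddof=1) if draws.size > 1 else np.nan
    table = pd.DataFrame(
        {
            "candidate": names,
            "frequency": freq,
            "ensemble_coef": ens_mean,
            "ensemble_se": ens_se,
        }
    )
    return AveragedModel(
        table=table,
        selected=[names[j] for j in final_idx],
        cutoff=cutoff,
        replicates=valid,
        seed=seed,
        n_skipped=skipped,
        supports=supports,
    )


def cutoff_sensitivity(
    design: DesignSpec,
    data: pd.DataFrame,
    cutoffs=(65.0, 70.0, 75.0, 80.0),
    B: int = 5000,
    seed: int = 0,
    selector: str = "adaptive_lasso",
) -> pd.DataFrame:
    """Selected sets across a range of frequency cutoffs (one bootstrap run).

    Returns one row per cutoff with the selected set and a ``stable`` flag
    that is True when every cutoff yields the same set.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff list")
    base = bootstrap_model_average(design, data, B=B, cutoff=min(cutoffs), seed=seed,
                                   selector=selector)
    freq = base.table.set_index("candidate")["frequency"]
    sets = {c: tuple(sorted(freq.index[freq >= c])) for c in cutoffs}
    stable = len(set(sets.values())) == 1
    return pd.DataFrame(
        {
            "cutoff": cutoffs,
            "selected": [", ".join(sets[c]) for c in cutoffs],
            "stable": stable,
        }
    )


def penalty_comparison(
    design: DesignSpec,
    data: pd.DataFrame,
    B: int = 500,
    cutoff: float = 70.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Adaptive LASSO vs ridge vs elastic net inside the same bootstrap wrapper."""
    rows = []
    for penalty in ("adaptive_lasso", "ridge", "elastic_net"):
        avg = bootstrap_model_average(design, data, B=B, cutoff=cutoff, seed=seed,
                                      selector=penalty)
        rows.append({"penalty": penalty, "selected": ", ".join(sorted(avg.selected))})
    out = pd.DataFrame(rows)
    out["identical"] = out["selected"].nunique() == 1
    return out
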