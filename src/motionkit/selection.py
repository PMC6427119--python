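"""Discriminant-parameter selection and score-oriented scaling.

Workflow: kinematic parameters from patient (PD) performances are first
normalized by the healthy-control (HC) group means, so every parameter
equals 1 at the HC reference; count-valued parameters with a natural zero
(PM by default) are passed through unchanged.  An elastic-net regression
against the clinical scores screens out irrelevant parameters (the L1/L2
mix keeps groups of correlated parameters together); a non-parametric
Spearman rank screen (|rho| > 0.3, p < 0.05) respects the ordinal nature
of the scores; and a Mann-Whitney U test validates each parameter's
PD-vs-HC discriminant power.  For classifier input every parameter is
mapped monotonically to [0, 1] so 0 is the healthy reference and 1 the
worst observed value (parameters that decrease with severity are reversed
by a reciprocal first).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .errors import UndefinedStatisticError


@dataclass
class FeatureTable:
    """Rows = performances; named parameter columns + group and score.

    ``group`` holds 'HC'/'PD' labels; ``score`` the clinical severity
    (ordinal class, or a subscale sum for the sway task).
    ``exclude_normalize`` lists columns exempt from HC-mean normalization.
    """

    data: pd.DataFrame
    group: np.ndarray
    score: np.ndarray
    exclude_normalize: tuple[str, ...] = ("PM",)
    hc_means: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        self.score = np.asarray(self.score, dtype=float)
        if len(self.data) != len(self.group) or len(self.data) != len(self.score):
            raise ValueError("data / group / score length mismatch")
        if self.data.isna().any().any():
            raise ValueError("missing cells in feature table")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            self.data[list(names)].copy(), self.group, self.score,
            self.exclude_normalize, self.hc_means,
        )


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Divide each parameter by its HC-group mean (exempt columns pass through).

    Idempotent on an already HC-referenced table: the HC mean of a
    normalized column is 1.
    """
    hc = table.group == "HC"
    if not np.any(hc):
        raise ValueError("no HC rows: cannot normalize")
    out = table.data.copy()
    means: dict[str, float] = {}
    for col in out.columns:
        if col in table.exclude_normalize:
            means[col] = 1.0
            continue
        m = float(out.loc[hc, col].mean())
        if m == 0.0:
            raise UndefinedStatisticError(f"HC mean of {col!r} is zero")
        out[col] = out[col] / m
        means[col] = m
    return FeatureTable(
        out, table.group, table.score, table.exclude_normalize, hc_means=means
    )


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

def elastic_net_select(
    table: FeatureTable,
    l1_ratio: float = 0.5,
    cv: int = 10,
    rule: str = "1se",
    seed: int = 0,
    n_alphas: int = 100,
) -> list[str]:
    """Parameters with nonzero elastic-net coefficient at the CV-chosen penalty.

    Features are standardized and the response centered before the fit.
    ``rule='1se'`` picks the strongest penalty whose mean CV error is within
    one standard error of the minimum (parsimonious); ``rule='min'`` picks
    the error-minimizing penalty.  Deterministic given ``seed``.
    """
    X = table.data.to_numpy(dtype=float)
    y = table.score
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("constant score: elastic net undefined")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features")
    sd = X.std(axis=0)
    keepable = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, keepable] = (X[:, keepable] - X[:, keepable].mean(axis=0)) / sd[keepable]
    yc = y - y.mean()

    folds = KFold(n_splits=min(cv, len(y)), shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=l1_ratio, alphas=n_alphas, cv=folds, max_iter=50_000
    ).fit(Xs, yc)

    if rule == "min":
        alpha = enet.alpha_
    elif rule == "1se":
        mse = enet.mse_path_            # (n_alphas, n_folds)
        mean = mse.mean(axis=-1)
        se = mse.std(axis=-1, ddof=1) / math.sqrt(mse.shape[-1])
        i_min = int(np.argmin(mean))
        limit = mean[i_min] + se[i_min]
        ok = np.flatnonzero(mean <= limit)
        alpha = float(enet.alphas_[ok[0]])  # alphas_ is descending: first = strongest
    else:
        raise ValueError("rule must be 'min' or '1se'")

    coef = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000).fit(Xs, yc).coef_
    return [n for n, c in zip(table.names, coef) if abs(c) > 1e-8]


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Spearman rho = Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def _spearman_p(rho: float, x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    if not np.isfinite(rho):
        return float("nan")
    if n <= 8:  # exact permutation null (n! enumerable)
        ry = stats.rankdata(y)
        count, total = 0, 0
        for perm in itertools.permutations(stats.rankdata(x)):
            r = np.corrcoef(np.asarray(perm), ry)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return count / total
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def spearman_screen(
    table: FeatureTable, rho_min: float = 0.3, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-parameter Spearman rank correlation against the score.

    Returns a frame with columns ``rho``, ``p``, ``keep`` (keep requires
    |rho| > rho_min AND p < alpha).  Constant columns get NaN and are never
    kept.
    """
    if len(table.data) < 5:
        raise ValueError("need >= 5 paired observations")
    rows = {}
    for col in table.names:
        x = table.data[col].to_numpy(dtype=float)
        rho = _spearman_rho(x, table.score)
        p = _spearman_p(rho, x, table.score)
        keep = bool(np.isfinite(rho) and abs(rho) > rho_min and p < alpha)
        rows[col] = {"rho": rho, "p": p, "keep": keep}
    return pd.DataFrame.from_dict(rows, orient="index")


def mannwhitney_validate(table: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test of each parameter, PD vs HC.

    Uses the normal approximation with tie correction; Z is signed by the
    direction of the PD shift (positive when PD values tend larger).
    """
    pd_mask = table.group == "PD"
    hc_mask = table.group == "HC"
    n1, n2 = int(pd_mask.sum()), int(hc_mask.sum())
    if n1 < 3 or n2 < 3:
        raise ValueError(f"each group needs >= 3 members (PD={n1}, HC={n2})")
    rows = {}
    for col in table.names:
        x = table.data[col].to_numpy(dtype=float)
        ranks = stats.rankdata(x)
        u_pd = float(ranks[pd_mask].sum() - n1 * (n1 + 1) / 2)
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, counts = np.unique(x, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:  # all values equal: no separation at all
            rows[col] = {"Z": 0.0, "p": 1.0, "significant": False}
            continue
        z = (u_pd - mu) / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
        rows[col] = {"Z": z, "p": p, "significant": bool(p < alpha)}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Combined selection + classifier scaling
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-parameter selection diagnostics and the final selected set."""

    stats: pd.DataFrame          # en_retained, rho, rho_p, Z, U_p, selected
    selected: list[str]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "parameters": self.stats.reset_index()
            .rename(columns={"index": "name"})
            .to_dict(orient="records"),
        }


def select_features(
    table: FeatureTable,
    l1_ratio: float = 0.5,
    rho_min: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> SelectionReport:
    """Full pipeline: HC normalization, elastic net, Spearman screen, U test.

    A parameter is selected iff the elastic net retains it AND it passes
    the Spearman screen; the U test is reported as validation.
    """
    norm = table if table.hc_means is not None else normalize_features(table)
    retained = set(elastic_net_select(norm, l1_ratio=l1_ratio, seed=seed))
    screen = spearman_screen(norm, rho_min=rho_min, alpha=alpha)
    utest = mannwhitney_validate(norm, alpha=alpha)
    frame = pd.DataFrame(
        {
            "en_retained": [n in retained for n in norm.names],
            "rho": screen["rho"],
            "rho_p": screen["p"],
            "Z": utest["Z"],
            "U_p": utest["p"],
        },
        index=norm.names,
    )
    frame["selected"] = frame["en_retained"] & screen["keep"]
    return SelectionReport(
        stats=frame, selected=[n for n in norm.names if frame.loc[n, "selected"]]
    )


@dataclass
class ScalingModel:
    """Severity-monotone [0, 1] map fitted on a normalized training table.

    Parameters increasing with severity map as (p - 1)/(p_max - 1);
    decreasing ones are reversed by a reciprocal first.  Exempt (count)
    columns are min-max scaled from 0.  Observed training extrema are
    stored so new instances clip instead of extrapolating.
    """

    direction: dict[str, int]
    p_extreme: dict[str, float]   # p_max (increasing/exempt) or p_min (decreasing)
    score_min: float
    score_max: float
    exempt: tuple[str, ...]

    def apply(self, data: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in self.direction:
            p = data[col].to_numpy(dtype=float)
            ext = self.p_extreme[col]
            if col in self.exempt:
                out[col] = np.clip(p / ext, 0.0, 1.0)
            elif self.direction[col] > 0:
                out[col] = np.clip((p - 1.0) / (ext - 1.0), 0.0, 1.0)
            else:
                q = 1.0 / p
                q_max = 1.0 / ext
                out[col] = np.clip((q - 1.0) / (q_max - 1.0), 0.0, 1.0)
        return pd.DataFrame(out, index=data.index)

    def apply_scores(self, score: np.ndarray) -> np.ndarray:
        span = self.score_max - self.score_min
        return np.clip((np.asarray(score, float) - self.score_min) / span, 0.0, 1.0)


def scale_for_classifier(
    table: FeatureTable, directions: Mapping[str, int] | None = None
) -> tuple[pd.DataFrame, np.ndarray, ScalingModel]:
    """Scale a normalized table into [0, 1] for classifier input.

    ``directions`` maps parameter name to +1 (worsens upward) or -1
    (worsens downward); by default the sign of the Spearman correlation
    with the score is used.  Returns (scaled features, scaled scores,
    fitted ScalingModel).
    """
    if table.hc_means is None:
        raise ValueError("table must be HC-normalized first (normalize_features)")
    if directions is None:
        screen = spearman_screen(table, rho_min=0.0, alpha=1.0)
        directions = {
            n: (1 if screen.loc[n, "rho"] >= 0 else -1) for n in table.names
        }
    dir_map: dict[str, int] = {}
    extreme: dict[str, float] = {}
    for col in table.names:
        p = table.data[col].to_numpy(dtype=float)
        d = int(directions[col])
        dir_map[col] = d
        if col in table.exclude_normalize:
            ext = float(p.max())
            if ext <= 0:
                raise UndefinedStatisticError(f"{col!r}: no spread above zero")
        elif d > 0:
            ext = float(p.max())
            if ext <= 1.0:
                raise UndefinedStatisticError(f"{col!r}: max does not exceed HC reference")
        else:
            ext = float(p.min())
            if ext >= 1.0 or ext <= 0:
                raise UndefinedStatisticError(f"{col!r}: min not below HC reference")
        extreme[col] = ext
    s_min, s_max = float(table.score.min()), float(table.score.max())
    if s_max == s_min:
        raise UndefinedStatisticError("constant score: cannot scale")
    model = ScalingModel(
        direction=dir_map,
        p_extreme=extreme,
        score_min=s_min,
        score_max=s_max,
        exempt=table.exclude_normalize,
    )
    return model.apply(table.data), model.apply_scores(table.score), model
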