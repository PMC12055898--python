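"""Design-of-experiments machinery: Box-Behnken designs, ANOVA variance
shares, linear response surfaces and normalised-absolute-error calibration.

The two-stage parameter study works on coded factor levels in {-1, 0, +1}
decoded as ``value = baseline * (1 + code * half_range)``: a six-factor
screening at +/-20% around the baseline tissue parameters, then a
four-factor response-surface stage at +/-50% whose fitted surfaces (in the
matrix and cement-line toughness) are compared against experimental peak
force, tortuosity and J_Ic to pick the best parameter pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "AnovaTable",
    "ResponseSurfaceModel",
    "CalibrationResult",
    "box_behnken",
    "run_design",
    "anova_tss",
    "fit_response_surface",
    "calibrate",
]


@dataclass(frozen=True)
class FactorSpec:
    """One design factor: name, baseline value and relative half-range."""

    name: str
    baseline: float
    half_range: float

    def __post_init__(self) -> None:
        if self.baseline <= 0.0:
            raise ValueError("baseline must be positive")
        if not 0.0 < self.half_range < 1.0:
            raise ValueError("half_range must lie in (0, 1)")

    def decode(self, code):
        return self.baseline * (1.0 + np.asarray(code, dtype=float) * self.half_range)


@dataclass
class DesignMatrix:
    """Coded Box-Behnken runs plus their decoded physical values."""

    factors: list  # list[FactorSpec]
    coded: pd.DataFrame  # columns = factor names, values in {-1, 0, 1}
    run_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.run_ids:
            self.run_ids = [f"run{i:03d}" for i in range(len(self.coded))]

    def __len__(self) -> int:
        return len(self.coded)

    @property
    def names(self) -> list:
        return [f.name for f in self.factors]

    def decoded(self) -> pd.DataFrame:
        out = {}
        for f in self.factors:
            out[f.name] = f.decode(self.coded[f.name].to_numpy())
        return pd.DataFrame(out, index=self.coded.index)


# classical Box-Behnken block structures: which factors are at +/-1 together
_BB_PAIR_RANGE = (3, 4, 5)
_BB_TRIPLES = {
    6: [(0, 1, 3), (1, 2, 4), (2, 3, 5), (3, 4, 0), (4, 5, 1), (5, 0, 2)],
    7: [(3, 4, 5), (0, 5, 6), (1, 4, 6), (0, 1, 3), (2, 3, 6), (0, 2, 4), (1, 2, 5)],
}


def box_behnken(factors: list, n_center: int = 1) -> DesignMatrix:
    """Construct a three-level Box-Behnken design.

    For 3-5 factors the design uses the classical two-factor +/-1 blocks
    (4 runs per factor pair); for 6-7 factors the three-factor blocks
    (8 runs per triple).  ``n_center`` all-zero rows are appended.  Run
    counts: k=3 -> 12, k=4 -> 24, k=5 -> 40, k=6 -> 48, k=7 -> 56 edge
    runs plus the centre repeats.  Ordering is deterministic.
    """
    k = len(factors)
    if not 3 <= k <= 7:
        raise ValueError(f"Box-Behnken construction supports 3-7 factors, got {k}")
    rows = []
    if k in _BB_PAIR_RANGE:
        for i, j in itertools.combinations(range(k), 2):
            for si, sj in itertools.product((-1, 1), repeat=2):
                row = [0] * k
                row[i], row[j] = si, sj
                rows.append(row)
    else:
        for triple in _BB_TRIPLES[k]:
            for signs in itertools.product((-1, 1), repeat=3):
                row = [0] * k
                for idx, s in zip(triple, signs):
                    row[idx] = s
                rows.append(row)
    rows.extend([[0] * k for _ in range(n_center)])
    coded = pd.DataFrame(rows, columns=[f.name for f in factors])
    return DesignMatrix(factors=list(factors), coded=coded)


def run_design(
    design: DesignMatrix,
    evaluate,
    cache_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Evaluate every design run through ``evaluate(params: dict) -> dict``.

    Returns one outcome row per run (columns = outcome names plus a
    ``failed`` flag); failed runs carry NaN outcomes rather than being
    dropped.  With ``cache_dir`` set, completed rows are cached as CSV
    keyed by run id, so an interrupted design resumes where it stopped.
    """
    decoded = design.decoded()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    records = []
    n_failed = 0
    for run_id, (_, row) in zip(design.run_ids, decoded.iterrows()):
        csv = cache / f"{run_id}.csv" if cache is not None else None
        if csv is not None and csv.exists():
            rec = pd.read_csv(csv).iloc[0].to_dict()
        else:
            params = row.to_dict()
            try:
                out = evaluate(params)
                rec = {"run_id": run_id, **params, **out, "failed": False}
            except Exception as exc:  # noqa: BLE001 -- flagged, not dropped
                rec = {"run_id": run_id, **params, "failed": True, "error": str(exc)}
            if csv is not None:
                pd.DataFrame([rec]).to_csv(csv, index=False)
        if rec.get("failed"):
            n_failed += 1
        records.append(rec)
    if n_failed == len(records):
        raise RuntimeError("all design runs failed")
    out = pd.DataFrame(records)
    out["failed"] = out["failed"].astype(bool)
    return out


@dataclass
class AnovaTable:
    """Per-term sums of squares, variance shares and p-values."""

    table: pd.DataFrame  # index = term, columns: SS, TSS, p, significant
    ss_total: float
    degenerate: bool = False

    def share(self, term: str) -> float:
        return float(self.table.loc[term, "TSS"])

    def top_factors(self, n: int = 2) -> list:
        return list(self.table.sort_values("TSS", ascending=False).index[:n])


def anova_tss(
    design: DesignMatrix,
    outcomes: pd.Series | np.ndarray,
    interactions: bool = False,
    alpha: float = 0.05,
) -> AnovaTable:
    """Type-II ANOVA variance shares TSS = SS_term / SS_total.

    Factors enter as continuous linear terms on their coded levels;
    pairwise interactions are included on request.  A constant outcome is
    flagged degenerate and all shares are reported as zero.
    """
    y = np.asarray(outcomes, dtype=float)
    data = design.coded.copy()
    data.columns = [f"f_{c}" for c in data.columns]
    data["y"] = y
    valid = np.isfinite(y)
    if not valid.all():
        data = data.loc[valid]
        y = y[valid]
    ss_total = float(((y - y.mean()) ** 2).sum())
    names = design.names
    terms = [f"f_{n}" for n in names]
    if interactions:
        terms += [
            f"f_{a}:f_{b}" for a, b in itertools.combinations(names, 2)
        ]
    if len(data) <= len(terms) + 1:
        raise ValueError("need more runs than model terms")
    if ss_total <= 1e-300:
        table = pd.DataFrame(
            {"SS": 0.0, "TSS": 0.0, "p": np.nan, "significant": False},
            index=[t.replace("f_", "").replace(":f_", ":") for t in terms],
        )
        return AnovaTable(table=table, ss_total=0.0, degenerate=True)
    model = smf.ols("y ~ " + " + ".join(terms), data=data).fit()
    an = anova_lm(model, typ=2)
    rows = {}
    for t in terms:
        label = t.replace("f_", "").replace(":f_", ":")
        ss = float(an.loc[t, "sum_sq"])
        p = float(an.loc[t, "PR(>F)"])
        rows[label] = {
            "SS": ss,
            "TSS": ss / ss_total,
            "p": p,
            "significant": p < alpha,
        }
    table = pd.DataFrame(rows).T
    table["significant"] = table["significant"].astype(bool)
    return AnovaTable(table=table, ss_total=ss_total)


@dataclass
class ResponseSurfaceModel:
    """Linear response surface for one outcome over a factor subset."""

    outcome: str
    factors: list  # list[FactorSpec] of the subset
    result: object  # statsmodels RegressionResults
    design_center: dict

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.result.conf_int(alpha)

    def _code(self, physical: dict) -> np.ndarray:
        return np.array(
            [
                (physical[f.name] / f.baseline - 1.0) / f.half_range
                for f in self.factors
            ]
        )

    def predict(self, physical: dict) -> float:
        """Prediction at a physical parameter point (decoded units)."""
        x = self._code(physical)
        params = self.result.params
        val = params["Intercept"] + sum(
            params[f"f_{f.name}"] * xi for f, xi in zip(self.factors, x)
        )
        return float(val)


def fit_response_surface(
    design: DesignMatrix,
    outcomes: pd.DataFrame,
    outcome_names: list,
    factor_subset: list,
) -> dict:
    """Ordinary-least-squares linear surfaces per outcome.

    ``factor_subset`` names must be design factors.  Rows flagged failed
    are excluded.  Returns {outcome: ResponseSurfaceModel}.
    """
    sub = [f for f in design.factors if f.name in factor_subset]
    if len(sub) != len(factor_subset):
        missing = set(factor_subset) - {f.name for f in design.factors}
        raise ValueError(f"unknown factors {sorted(missing)}")
    ok = ~outcomes["failed"].to_numpy() if "failed" in outcomes else np.ones(len(outcomes), bool)
    data = design.coded.loc[ok].copy()
    data.columns = [f"f_{c}" for c in data.columns]
    surfaces = {}
    for name in outcome_names:
        data["y"] = outcomes.loc[ok, name].to_numpy(dtype=float)
        terms = " + ".join(f"f_{f.name}" for f in sub)
        model = smf.ols(f"y ~ {terms}", data=data).fit()
        if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            raise ValueError(f"rank-deficient design for outcome {name!r}")
        surfaces[name] = ResponseSurfaceModel(
            outcome=name,
            factors=sub,
            result=model,
            design_center={f.name: f.baseline for f in sub},
        )
    return surfaces


@dataclass
class CalibrationResult:
    """Arg-min of the normalised-absolute-error cost over a factor grid."""

    best: dict  # factor name -> calibrated physical value
    cost: float
    grid: pd.DataFrame  # columns: the two factors + 'cost'

    def as_tuple(self) -> tuple:
        return tuple(self.best.values())


def calibrate(
    surfaces: dict,
    targets: dict,
    grid_step: float = 0.01,
    factor_names: list | None = None,
) -> CalibrationResult:
    """Minimise ``sum_o |RS_o(theta) - y_o| / y_o`` on a regular grid.

    The grid spans the coded range [-1, +1] of the (two) calibration
    factors with physical spacing ``grid_step``; ties are broken towards
    the baseline point.  Targets must be positive.
    """
    for k, v in targets.items():
        if v <= 0.0:
            raise ValueError(f"target {k!r} must be positive")
    some_surface = next(iter(surfaces.values()))
    factors = some_surface.factors
    if factor_names is not None:
        factors = [f for f in factors if f.name in factor_names]
    axes = []
    for f in factors:
        lo = f.baseline * (1.0 - f.half_range)
        hi = f.baseline * (1.0 + f.half_range)
        n = int(round((hi - lo) / grid_step))
        axes.append(lo + grid_step * np.arange(n + 1))
    if any(len(ax) == 0 for ax in axes):
        raise ValueError("empty calibration grid")
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    cost = np.zeros(len(pts))
    for name, surf in surfaces.items():
        y = targets[name]
        params = surf.result.params
        pred = np.full(len(pts), float(params["Intercept"]))
        for j, f in enumerate(factors):
            code = (pts[:, j] / f.baseline - 1.0) / f.half_range
            pred += float(params[f"f_{f.name}"]) * code
        cost += np.abs(pred - y) / y
    best_cost = cost.min()
    ties = np.flatnonzero(cost <= best_cost + 1e-12)
    centre = np.array([f.baseline for f in factors])
    dist = np.linalg.norm(pts[ties] - centre, axis=1)
    pick = ties[np.argmin(dist)]
    grid = pd.DataFrame(pts, columns=[f.name for f in factors])
    grid["cost"] = cost
    return CalibrationResult(
        best={f.name: float(pts[pick, j]) for j, f in enumerate(factors)},
        cost=float(cost[pick]),
        grid=grid,
    )
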