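"""Mixed models of daily network position, tested by data-stream permutation.

Daily node metrics are modelled with a linear mixed model: fixed effects
are treatment (CORT vs control), observation day, sex, and the treatment
x day and treatment x sex interactions; random intercepts are individual,
nested within family, nested within room.  Parents carry no treatment and
are excluded.

Because network metrics of different birds are not independent, coefficient
significance comes from a constrained permutation of the underlying data
stream rather than from the model's asymptotic errors.  The group-by-
individual matrix is randomised by checkerboard swaps restricted to
(day, room) strata: pick two events in the same stratum and two birds each
present in exactly one of them, and exchange their memberships.  Swaps
preserve every event's size and every bird's number of events per stratum,
so gregariousness and sampling effort survive under the null.  A single
serial chain is run (burn-in, then one sample every ``swaps_per_step``
accepted swaps); at each sample the daily networks and metrics are rebuilt
and the identical model refitted.  The observed coefficient is then located
within the resulting permutation distribution (two-tailed around the
null's own centre by default, add-one estimator); because swaps preserve
sampling effort the null need not be centred at zero.

The validity contract of the permutation p is that the *same* fitting
routine is applied to observed and permuted data; estimator optimality is
not required.  A plain least-squares estimator is therefore offered next to
the mixed model for large permutation runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import network as _net
from .events import GroupByIndividual
from .network import AssociationMatrix
from .simulate import BirdRecord

__all__ = [
    "MetricModelSpec",
    "PermutationResult",
    "metrics_from_gbi",
    "fit_metric_model",
    "permute_stream",
    "permutation_test",
]

COEF_NAMES = ("Intercept", "treatment", "day_c", "sex_m",
              "treatment:day_c", "treatment:sex_m")


@dataclass(frozen=True)
class MetricModelSpec:
    """Which daily metric to model and how.

    estimator: "mixedlm" (REML linear mixed model with the nested random
    intercepts, falling back to simpler structures on singular fits) or
    "ols" (ordinary least squares; identical fixed-effect design).
    day_categorical: model day as a factor instead of a centred covariate.
    """

    response: str
    estimator: str = "mixedlm"
    day_categorical: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ("mixedlm", "ols"):
            raise ValueError("estimator must be 'mixedlm' or 'ols'")


@dataclass
class PermutationResult:
    coefficient: str
    observed: float
    null: np.ndarray
    p: float
    n_perms: int
    swaps_per_step: int
    burn_in: int
    seed: int


# ---------------------------------------------------------------------------
# fast daily metrics straight from a GBI matrix

def _daily_weight_matrices(
    mat: np.ndarray, days: np.ndarray, rooms: np.ndarray
) -> dict[int, np.ndarray]:
    same_room = rooms[:, None] == rooms[None, :]
    out: dict[int, np.ndarray] = {}
    for d in np.unique(days):
        x = mat[days == d].astype(np.float64)
        both = x.T @ x
        n_ev = np.diag(both).copy()
        union = n_ev[:, None] + n_ev[None, :] - both
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(union > 0, both / np.where(union > 0, union, 1.0), 0.0)
        np.fill_diagonal(w, 0.0)
        out[int(d)] = w * same_room
    return out


def _cv_rows(w: np.ndarray, rooms: np.ndarray) -> np.ndarray:
    """Per-node CV of edge weights to same-room others, zeros included."""
    n = w.shape[0]
    out = np.zeros(n)
    for room in np.unique(rooms):
        idx = np.flatnonzero(rooms == room)
        s = idx.size
        if s < 2:
            out[idx] = np.nan
            continue
        block = w[np.ix_(idx, idx)]
        m = block.sum(axis=1) / (s - 1)
        ex2 = (block ** 2).sum(axis=1) / (s - 1)
        var = np.maximum(ex2 - m ** 2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(m > 0, np.sqrt(var) / np.where(m > 0, m, 1.0), 0.0)
        out[idx] = cv
    return out


def metrics_from_gbi(
    gbi: GroupByIndividual,
    roster: Sequence[BirdRecord],
    metrics: Sequence[str] = ("degree", "strength"),
) -> pd.DataFrame:
    """Tidy (tag, day, metric...) table computed directly from a GBI.

    Degree, strength, social differentiation and parent association are
    computed with vectorised array operations (fast enough to sit inside a
    permutation loop); betweenness and eigenvector centrality go through
    the graph routines in :mod:`flocknet.network`.
    """
    rooms = np.asarray(gbi.rooms)
    days = gbi.days
    ev_rooms = gbi.event_rooms
    tags = gbi.tags
    by_tag = {b.tag: b for b in roster}
    wmats = _daily_weight_matrices(gbi.matrix, days, rooms)

    chick_idx: list[int] = []
    par_idx: list[tuple[int, int]] = []
    for j, t in enumerate(tags):
        b = by_tag[t]
        if b.role == "chick":
            pts = [k for k, u in enumerate(tags)
                   if by_tag[u].family_id == b.family_id and by_tag[u].role == "parent"]
            if len(pts) == 2:
                chick_idx.append(j)
                par_idx.append((pts[0], pts[1]))

    frames: list[pd.DataFrame] = []
    need_graph = {"betweenness", "betweenness_w", "eigenvector"} & set(metrics)
    for d, w in sorted(wmats.items()):
        cols: dict[str, np.ndarray] = {}
        if "degree" in metrics:
            cols["degree"] = (w > 0).sum(axis=1).astype(float)
        if "strength" in metrics:
            cols["strength"] = w.sum(axis=1)
        if "social_differentiation" in metrics:
            cols["social_differentiation"] = _cv_rows(w, rooms)
        if "parent_association" in metrics:
            pa = np.full(len(tags), np.nan)
            for j, (p1, p2) in zip(chick_idx, par_idx):
                pa[j] = 0.5 * (w[j, p1] + w[j, p2])
            cols["parent_association"] = pa
        if need_graph:
            a = AssociationMatrix(w, list(tags), list(gbi.rooms), scope=f"day {d}")
            if "betweenness" in metrics:
                cols["betweenness"] = _net.betweenness(a, weighted=False)
            if "betweenness_w" in metrics:
                cols["betweenness_w"] = _net.betweenness(a, weighted=True)
            if "eigenvector" in metrics:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cols["eigenvector"] = _net.eigenvector_centrality(a)
        frame = pd.DataFrame(cols)
        frame.insert(0, "day", d)
        frame.insert(0, "tag", tags)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# model fitting

def build_model_frame(metric_df: pd.DataFrame, roster: Sequence[BirdRecord],
                      response: str) -> pd.DataFrame:
    """Chick-only modelling frame with coded covariates."""
    by_tag = {b.tag: b for b in roster}
    df = metric_df[metric_df["tag"].map(lambda t: by_tag[t].role) == "chick"].copy()
    df = df.dropna(subset=[response])
    df["value"] = df[response].astype(float)
    df["treatment"] = df["tag"].map(lambda t: 1.0 if by_tag[t].treatment == "CORT" else 0.0)
    df["sex_m"] = df["tag"].map(lambda t: 1.0 if by_tag[t].sex == "M" else 0.0)
    df["family_id"] = df["tag"].map(lambda t: by_tag[t].family_id)
    df["room_id"] = df["tag"].map(lambda t: by_tag[t].room_id)
    df["day_c"] = df["day"] - df["day"].mean()
    return df


def _design(df: pd.DataFrame, day_categorical: bool) -> tuple[np.ndarray, list[str]]:
    if not day_categorical:
        cols = [np.ones(len(df)), df["treatment"], df["day_c"], df["sex_m"],
                df["treatment"] * df["day_c"], df["treatment"] * df["sex_m"]]
        names = list(COEF_NAMES)
    else:
        days = sorted(df["day"].unique())
        cols = [np.ones(len(df)), df["treatment"].to_numpy()]
        names = ["Intercept", "treatment"]
        for d in days[1:]:
            cols.append((df["day"] == d).astype(float).to_numpy())
            names.append(f"day[{d}]")
        cols += [df["sex_m"].to_numpy()]
        names += ["sex_m"]
        for d in days[1:]:
            cols.append(((df["day"] == d).astype(float) * df["treatment"]).to_numpy())
            names.append(f"treatment:day[{d}]")
        cols.append((df["treatment"] * df["sex_m"]).to_numpy())
        names.append("treatment:sex_m")
    X = np.column_stack([np.asarray(c, dtype=float) for c in cols])
    return X, names


def _fit_ols(df: pd.DataFrame, day_categorical: bool) -> tuple[dict[str, float], dict]:
    X, names = _design(df, day_categorical)
    beta, *_ = np.linalg.lstsq(X, df["value"].to_numpy(dtype=float), rcond=None)
    return dict(zip(names, beta)), {"method": "ols", "converged": True}


def _fit_mixedlm(df: pd.DataFrame, day_categorical: bool,
                 start_params=None) -> tuple[dict[str, float], dict]:
    import statsmodels.formula.api as smf

    fixed = ("value ~ treatment*C(day) + treatment*sex_m" if day_categorical
             else "value ~ treatment*day_c + treatment*sex_m")
    multi_room = df["room_id"].nunique() > 1
    multi_fam = df["family_id"].nunique() > 1

    # nested random-intercept structures, richest first; fall back by
    # dropping the innermost variance component when a fit fails
    attempts: list[tuple[str, str, dict | None]] = []
    if multi_room and multi_fam:
        attempts.append(("room/family/bird", "room_id",
                         {"family": "0 + C(family_id)", "bird": "0 + C(tag)"}))
        attempts.append(("room/family", "room_id",
                         {"family": "0 + C(family_id)"}))
    if multi_fam:
        attempts.append(("family/bird", "family_id", {"bird": "0 + C(tag)"}))
        attempts.append(("family", "family_id", None))
    attempts.append(("bird", "tag", None))

    for label, groups, vc in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(fixed, df, groups=df[groups],
                                 re_formula="1", vc_formula=vc)
                sp = None
                if start_params is not None and \
                        len(start_params) == len(md.start_params):
                    sp = start_params
                res = md.fit(reml=True, method="lbfgs", maxiter=200,
                             start_params=sp)
            if not np.all(np.isfinite(np.asarray(res.fe_params))):
                continue
            rec = {"method": f"mixedlm[{label}]",
                   "converged": bool(res.converged),
                   "params": np.asarray(res.params)}
            return {k: float(v) for k, v in res.fe_params.items()}, rec
        except Exception:
            continue
    coefs, rec = _fit_ols(df, day_categorical)
    rec["method"] = "ols[fallback]"
    return coefs, rec


def fit_metric_model(
    metric_df: pd.DataFrame,
    roster: Sequence[BirdRecord],
    spec: MetricModelSpec,
    start_params=None,
) -> tuple[dict[str, float], dict]:
    """Fit the daily-metric model; returns (fixed-effect coefficients,
    fit record).

    The fit record carries the estimator actually used — the mixed-model
    path degrades gracefully through simpler random-effect structures and
    finally to OLS if every mixed fit fails, which is recorded rather than
    raised: the permutation framework needs a coefficient from every draw
    produced by the same routine.
    """
    df = build_model_frame(metric_df, roster, spec.response)
    if df["treatment"].nunique() < 2:
        raise ValueError("need chicks of both treatments")
    if df["day"].nunique() < 2 and not spec.day_categorical:
        raise ValueError("need at least two days of data")
    if spec.estimator == "ols":
        return _fit_ols(df, spec.day_categorical)
    return _fit_mixedlm(df, spec.day_categorical, start_params=start_params)


# ---------------------------------------------------------------------------
# constrained stream permutation

def _stratum_labels(gbi: GroupByIndividual,
                    include_feeder: bool = False) -> np.ndarray:
    keys = []
    for e in gbi.events:
        key = (e.day, e.room_id) + ((e.feeder_id,) if include_feeder else ())
        keys.append(key)
    uniq = {k: i for i, k in enumerate(sorted(set(keys), key=str))}
    return np.asarray([uniq[k] for k in keys])


def _any_swap_possible(mat: np.ndarray, strata: np.ndarray) -> bool:
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        if rows.size < 2:
            continue
        for ii in range(rows.size):
            for jj in range(ii + 1, rows.size):
                r1, r2 = mat[rows[ii]], mat[rows[jj]]
                if np.any(r1 & ~r2) and np.any(r2 & ~r1):
                    return True
    return False


def _do_swaps(mat: np.ndarray, strata: np.ndarray, n_swaps: int,
              rng: np.random.Generator, stratum_events: list[np.ndarray],
              max_attempts: int | None = None) -> None:
    """Accept n_swaps checkerboard swaps in place."""
    if n_swaps <= 0:
        return
    eligible = [ev for ev in stratum_events if ev.size >= 2]
    if not eligible:
        raise ValueError("no stratum holds two events; stream cannot be permuted")
    accepted = 0
    attempts = 0
    cap = max_attempts or (1000 + 500 * n_swaps)
    while accepted < n_swaps:
        attempts += 1
        if attempts > cap:
            if not _any_swap_possible(mat, strata):
                raise ValueError("degenerate stream: no eligible checkerboard swap")
            cap *= 2
        ev = eligible[rng.integers(len(eligible))]
        e1, e2 = ev[rng.integers(ev.size)], ev[rng.integers(ev.size)]
        if e1 == e2:
            continue
        r1, r2 = mat[e1], mat[e2]
        only1 = np.flatnonzero(r1 & ~r2)
        only2 = np.flatnonzero(r2 & ~r1)
        if only1.size == 0 or only2.size == 0:
            continue
        b1 = only1[rng.integers(only1.size)]
        b2 = only2[rng.integers(only2.size)]
        mat[e1, b1], mat[e1, b2] = 0, 1
        mat[e2, b2], mat[e2, b1] = 0, 1
        accepted += 1


def permute_stream(
    gbi: GroupByIndividual,
    n_swaps: int,
    seed: int | np.random.Generator = 0,
    include_feeder: bool = False,
) -> GroupByIndividual:
    """Return a copy of the GBI after ``n_swaps`` accepted checkerboard
    swaps within (day, room) strata (optionally also within feeder).

    Row sums (event sizes) and per-stratum column sums (each bird's event
    count) are conserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    strata = _stratum_labels(gbi, include_feeder)
    stratum_events = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    mat = gbi.matrix.astype(bool).copy()
    _do_swaps(mat, strata, n_swaps, rng, stratum_events)
    return GroupByIndividual(mat.astype(np.int8), gbi.events, list(gbi.tags),
                             list(gbi.rooms), list(gbi.unobserved))


def permutation_test(
    gbi: GroupByIndividual,
    roster: Sequence[BirdRecord],
    spec: MetricModelSpec,
    n_perms: int = 1000,
    swaps_per_step: int = 100,
    burn_in: int = 1000,
    seed: int = 0,
    include_feeder: bool = False,
    warm_start: bool = True,
    coefficients: Sequence[str] | None = None,
    tail: str = "two",
) -> dict[str, PermutationResult]:
    """Data-stream permutation test of the daily-metric model coefficients.

    The observed GBI is scored, the chain is burnt in, and after every
    ``swaps_per_step`` accepted swaps the daily networks and metrics are
    rebuilt from the permuted GBI and the identical model refitted.  Draws
    whose fit fails are discarded (aborting if more than 5% fail).  With
    ``swaps_per_step=0`` every null draw equals the observed fit and every
    p-value is 1 by construction.
    """
    rng = np.random.default_rng(seed)
    metric = spec.response
    obs_df = metrics_from_gbi(gbi, roster, metrics=(metric,))
    obs_coefs, obs_rec = fit_metric_model(obs_df, roster, spec)
    start = obs_rec.get("params") if warm_start else None

    strata = _stratum_labels(gbi, include_feeder)
    stratum_events = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    mat = gbi.matrix.astype(bool).copy()
    if burn_in > 0 and swaps_per_step > 0:
        _do_swaps(mat, strata, burn_in, rng, stratum_events)

    names = list(obs_coefs) if coefficients is None else list(coefficients)
    null = {nm: [] for nm in names}
    failures = 0
    for _ in range(n_perms):
        if swaps_per_step > 0:
            _do_swaps(mat, strata, swaps_per_step, rng, stratum_events)
        perm_gbi = GroupByIndividual(mat.astype(np.int8), gbi.events,
                                     list(gbi.tags), list(gbi.rooms))
        try:
            df = metrics_from_gbi(perm_gbi, roster, metrics=(metric,))
            coefs, _ = fit_metric_model(df, roster, spec, start_params=start)
        except Exception:
            failures += 1
            if failures > 0.05 * n_perms:
                raise RuntimeError(
                    f"more than 5% of permuted fits failed ({failures})")
            continue
        for nm in names:
            null[nm].append(coefs[nm])

    out: dict[str, PermutationResult] = {}
    for nm in names:
        arr = np.asarray(null[nm])
        out[nm] = PermutationResult(
            coefficient=nm, observed=float(obs_coefs[nm]), null=arr,
            p=_perm_p(float(obs_coefs[nm]), arr, tail), n_perms=int(arr.size),
            swaps_per_step=swaps_per_step, burn_in=burn_in, seed=seed)
    return out


def _perm_p(observed: float, null: np.ndarray, tail: str = "two") -> float:
    """Permutation p with the add-one estimator.

    The observed coefficient is located within the permutation
    distribution.  Because constrained stream swaps preserve each bird's
    sampling effort, the null distribution need not be centred at zero, so
    the two-tailed count is taken around the null's own centre:
    k = #{|null - centre| >= |observed - centre|}.  One-tailed options
    count the upper or lower tail directly.
    """
    if null.size == 0:
        return 1.0
    if tail == "greater":
        k = int(np.sum(null >= observed - 1e-12))
    elif tail == "less":
        k = int(np.sum(null <= observed + 1e-12))
    elif tail == "two":
        c = float(null.mean())
        k = int(np.sum(np.abs(null - c) >= abs(observed - c) - 1e-12))
    else:
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    return (k + 1) / (null.size + 1)
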