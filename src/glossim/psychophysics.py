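"""Experiment-analysis layer: simulated two-alternative forced choice (2AFC)
from model gloss predictions, the stimulus-selection algorithms for the
relief-sequence and scene-pair experiments, the rating/ranking/choice data
transforms, model-evaluation metrics with an inter-observer noise ceiling,
and a synthetic-observer generator that emulates groups of human observers
so the full pipeline is testable without archived behavioral data.

Synthetic observers follow a standard psychometric choice model
``P(choose A) = lapse/2 + (1 - lapse) * logistic(beta * (g_A - g_B))`` and an
ordinal rating model (monotone mapping of true gloss plus Gaussian criterion
noise, cut by five ordered criteria into ratings 1-6).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SequenceProfile", "ChoiceDataset", "RatingDataset", "ObserverParams",
    "simulate_2afc", "two_way_anova_interaction", "rank_sequences_by_disagreement",
    "classify_constancy_pattern", "select_percentile_pairs", "normalize_unit_range",
    "choices_to_proportions", "model_delta_for_pairs", "ranks_to_positions",
    "evaluate_predictions", "noise_ceiling", "synthetic_observer",
    "fit_observer_params", "default_observer_population",
]


@dataclass
class SequenceProfile:
    proportions: np.ndarray  # per-step proportion judged glossier
    source: str = "model_simulation"  # human | synthetic_observer | model_simulation
    n_comparisons: int = 0

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=np.float64)
        if self.proportions.min() < -1e-12 or self.proportions.max() > 1 + 1e-12:
            raise ValueError("proportions must lie in [0, 1]")


@dataclass
class ChoiceDataset:
    """Aggregated pairwise choices: one row per (observer, pair)."""

    table: pd.DataFrame  # columns: observer, pair, a, b, n_a, n_b

    def __post_init__(self):
        t = self.table
        if (t["n_a"] < 0).any() or (t["n_b"] < 0).any():
            raise ValueError("negative counts")


@dataclass
class RatingDataset:
    table: pd.DataFrame  # columns: observer, image, repetition, rating

    def __post_init__(self):
        r = self.table["rating"]
        if (r < 1).any() or (r > 6).any():
            raise ValueError("ratings must lie on the 1-6 scale")


@dataclass
class ObserverParams:
    beta: float  # choice steepness per unit decision value
    lapse: float = 0.0
    criteria: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0)  # 5 ordered rating thresholds
    rating_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0 <= self.lapse <= 0.2:
            raise ValueError("lapse must lie in [0, 0.2]")
        if not np.all(np.diff(self.criteria) > 0):
            raise ValueError("criteria must be strictly increasing")


# ---------------------------------------------------------------------------
# simulated 2AFC and sequence selection
# ---------------------------------------------------------------------------

def simulate_2afc(predictions) -> SequenceProfile:
    """Deterministic all-pairs 2AFC: the image with the higher predicted
    gloss wins each comparison; exact ties are split 0.5/0.5.  The per-image
    proportion of wins over its n-1 comparisons is returned (its mean over
    images is always exactly 0.5)."""
    g = np.asarray(predictions, dtype=np.float64)
    n = len(g)
    if n < 2:
        raise ValueError("need at least 2 images")
    wins = np.zeros(n)
    for i, j in itertools.combinations(range(n), 2):
        if g[i] > g[j]:
            wins[i] += 1
        elif g[j] > g[i]:
            wins[j] += 1
        else:
            wins[i] += 0.5
            wins[j] += 0.5
    return SequenceProfile(wins / (n - 1), source="model_simulation", n_comparisons=n - 1)


def two_way_anova_interaction(cells: np.ndarray) -> dict:
    """Balanced two-way fixed-effects ANOVA from a (levels_a, levels_b, reps)
    data array; returns F statistics for both main effects and the
    interaction.  Cells without replication (reps == 1) have no error term
    and are flagged with infinite F where the effect SS is positive."""
    y = np.asarray(cells, dtype=np.float64)
    a, b, r = y.shape
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)
    ss_a = b * r * np.sum((mean_a - grand) ** 2)
    ss_b = a * r * np.sum((mean_b - grand) ** 2)
    ss_ab = r * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_err = np.sum((y - mean_ab[:, :, None]) ** 2)
    df_a, df_b, df_ab, df_err = a - 1, b - 1, (a - 1) * (b - 1), a * b * (r - 1)
    out = {}
    for name, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b), ("interaction", ss_ab, df_ab)):
        if df_err <= 0 or ss_err == 0:
            f = np.inf if ss > 1e-15 else 0.0
            p = np.nan
        else:
            ms_err = ss_err / df_err
            f = (ss / df) / ms_err if df > 0 else np.nan
            p = float(stats.f.sf(f, df, df_err)) if np.isfinite(f) else np.nan
        out[f"F_{name}"] = float(f)
        out[f"p_{name}"] = p
        out[f"ss_{name}"] = float(ss)
    out["ss_error"] = float(ss_err)
    out["df_error"] = df_err
    return out


def rank_sequences_by_disagreement(profiles_model_a, profiles_model_b):
    """Rank candidate 7-step sequences by the model x relief interaction F.

    `profiles_model_a` / `_b` are lists (one per candidate sequence) of
    (instances, steps) arrays of simulated proportion-glossier values.
    Returns a list of (sequence index, interaction F) sorted by descending F.
    """
    if len(profiles_model_a) != len(profiles_model_b):
        raise ValueError("both models must cover the same candidate sequences")
    ranked = []
    for s, (pa, pb) in enumerate(zip(profiles_model_a, profiles_model_b)):
        pa = np.atleast_2d(np.asarray(pa, dtype=np.float64))
        pb = np.atleast_2d(np.asarray(pb, dtype=np.float64))
        if pa.shape[1] != pb.shape[1]:
            raise ValueError("step counts differ between models")
        reps = min(pa.shape[0], pb.shape[0])
        cells = np.stack([pa[:reps].T, pb[:reps].T], axis=0)  # (2, steps, reps)
        res = two_way_anova_interaction(cells)
        ranked.append((s, res["F_interaction"]))
    ranked.sort(key=lambda t: np.inf if np.isnan(t[1]) else -t[1])
    return ranked


def _poly_r2(x: np.ndarray, y: np.ndarray, degree: int):
    coef = np.polyfit(x, y, degree)
    pred = np.polyval(coef, x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0, coef  # constant profile: any fit through the mean is perfect
    return 1.0 - np.sum((y - pred) ** 2) / ss_tot, coef


def classify_constancy_pattern(profile) -> str:
    """Assign a 7-step proportion-glossier profile to a qualitative constancy
    group:

    * ``constant`` — range < 0.25 and linear fit R^2 > 0.70;
    * ``linear`` — range > 0.50 and linear R^2 > 0.90;
    * ``non_monotonic`` — range > 0.50, quadratic R^2 > 0.90, negative
      squared-term coefficient (inverted U);
    * ``nonlinear_upward`` — same with positive squared coefficient;
    * ``unclassified`` otherwise.

    Quadratic groups are evaluated before the linear group, so a strong
    quadratic that also fits a line moderately lands in its quadratic group.
    """
    y = np.asarray(profile, dtype=np.float64)
    x = np.arange(len(y), dtype=np.float64)
    rng_ = y.max() - y.min()
    lin_r2, _ = _poly_r2(x, y, 1)
    quad_r2, quad_coef = _poly_r2(x, y, 2)
    curved = abs(quad_coef[0]) > 1e-8  # an exact line is not "quadratic"
    if rng_ < 0.25 and lin_r2 > 0.70:
        return "constant"
    if rng_ > 0.50 and quad_r2 > 0.90 and curved and quad_coef[0] < 0:
        return "non_monotonic"
    if rng_ > 0.50 and quad_r2 > 0.90 and curved and quad_coef[0] > 0:
        return "nonlinear_upward"
    if rng_ > 0.50 and lin_r2 > 0.90:
        return "linear"
    return "unclassified"


def select_percentile_pairs(abs_deltas, k: int = 10) -> np.ndarray:
    """Indices of the pairs lying at each decile of the ascending |delta
    predicted gloss| ranking: the pair at rank ceil(j*n/k) for j = 1..k."""
    d = np.asarray(abs_deltas, dtype=np.float64)
    n = len(d)
    if n < k:
        raise ValueError(f"need at least {k} candidates")
    order = np.argsort(d, kind="stable")
    ranks = [int(np.ceil(j * n / k)) - 1 for j in range(1, k + 1)]
    return order[ranks]


# ---------------------------------------------------------------------------
# human-data transforms
# ---------------------------------------------------------------------------

def normalize_unit_range(values) -> np.ndarray:
    """Affine map of one participant's / one instance's values onto [0, 1]
    (constant input maps to all 0.5, with a warning flag via np.warnings)."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-15:
        import warnings

        warnings.warn("constant values: unit-range normalization returns 0.5")
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def choices_to_proportions(choices: ChoiceDataset, design: str):
    """Aggregate pairwise choices.

    ``design='sequence'``: per-image win proportion across pairings and
    repetitions, per observer; returns {observer: SequenceProfile}.
    ``design='pair'``: proportion A chosen minus 0.5 per pair (0 = perfect
    constancy, +0.5 = A always judged glossier); returns a DataFrame.
    """
    t = choices.table
    if design == "pair":
        grp = t.groupby(["observer", "pair"], sort=True)[["n_a", "n_b"]].sum()
        prop = grp["n_a"] / (grp["n_a"] + grp["n_b"])
        return (prop - 0.5).rename("centered_proportion").reset_index()
    if design != "sequence":
        raise ValueError("design must be 'sequence' or 'pair'")
    out = {}
    for obs, sub in t.groupby("observer", sort=True):
        images = sorted(set(sub["a"]) | set(sub["b"]))
        expected = {frozenset(p) for p in itertools.combinations(images, 2)}
        got = {frozenset((a, b)) for a, b in zip(sub["a"], sub["b"])}
        if expected - got:
            raise ValueError(f"incomplete pairing for observer {obs}")
        wins = {im: 0.0 for im in images}
        total = {im: 0.0 for im in images}
        for _, row in sub.iterrows():
            wins[row["a"]] += row["n_a"]
            wins[row["b"]] += row["n_b"]
            total[row["a"]] += row["n_a"] + row["n_b"]
            total[row["b"]] += row["n_a"] + row["n_b"]
        prof = np.array([wins[im] / total[im] for im in images])
        out[obs] = SequenceProfile(prof, source="human", n_comparisons=int(len(images) - 1))
    return out


def model_delta_for_pairs(pred_a, pred_b) -> np.ndarray:
    """Per-pair prediction differences scaled into [-0.5, 0.5] with the zero
    point preserved (difference divided by the max |difference|, times 0.5)."""
    d = np.asarray(pred_a, dtype=np.float64) - np.asarray(pred_b, dtype=np.float64)
    m = np.max(np.abs(d))
    if m == 0:
        raise ValueError("all prediction differences are zero")
    return d / m * 0.5


def ranks_to_positions(rankings: np.ndarray) -> np.ndarray:
    """Average rank position (1..n) per modulation step over repeated 5-image
    rankings.  `rankings[t, s]` is the position assigned to step s in trial t;
    each row must be a permutation of 1..n."""
    r = np.asarray(rankings, dtype=np.float64)
    n = r.shape[1]
    for row in r:
        if sorted(row.tolist()) != list(range(1, n + 1)):
            raise ValueError("each ranking must use each position exactly once")
    return r.mean(axis=0)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _logistic4(x, floor, ceiling, midpoint, slope):
    return floor + (ceiling - floor) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_logistic_link(x: np.ndarray, y: np.ndarray):
    """Least-squares 4-parameter logistic fit with multi-start initialization."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    spread = x.max() - x.min() or 1.0
    best = None
    for mid_q, slope0 in itertools.product((0.25, 0.5, 0.75), (1.0, 4.0, 10.0)):
        p0 = (y.min(), y.max(), np.quantile(x, mid_q), slope0 / spread)
        try:
            popt, _ = optimize.curve_fit(_logistic4, x, y, p0=p0, maxfev=5000)
        except RuntimeError:
            continue
        sse = np.sum((y - _logistic4(x, *popt)) ** 2)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("logistic link failed to converge from all starts")
    return best[1]


def evaluate_predictions(model_values, human_values_per_observer,
                         logistic_link: bool = False) -> dict:
    """Per-observer RMSE plus correlation/R^2 of model vs human values.

    Both sides are unit-range normalized first (model once, humans per
    observer).  With `logistic_link`, a 4-parameter logistic from model value
    to the observer-mean human value is fitted by least squares and its R^2
    reported as well.
    """
    m = normalize_unit_range(np.asarray(model_values, dtype=np.float64))
    obs = {k: normalize_unit_range(np.asarray(v, dtype=np.float64))
           for k, v in dict(human_values_per_observer).items()}
    for v in obs.values():
        if len(v) != len(m):
            raise ValueError("model/human stimulus sets must match")
    rmse = {k: float(np.sqrt(np.mean((m - v) ** 2))) for k, v in obs.items()}
    mean_human = np.mean(np.stack(list(obs.values())), axis=0)
    ss_tot = np.sum((mean_human - mean_human.mean()) ** 2)
    r = float(np.corrcoef(m, mean_human)[0, 1]) if m.std() > 0 else np.nan
    r2 = float(1.0 - np.sum((mean_human - m) ** 2) / ss_tot) if ss_tot > 0 else np.nan
    out = {"rmse_per_observer": rmse, "mean_rmse": float(np.mean(list(rmse.values()))),
           "pearson_r": r, "r2": r2}
    if logistic_link:
        popt = fit_logistic_link(m, mean_human)
        pred = _logistic4(m, *popt)
        out["logistic_r2"] = float(1.0 - np.sum((mean_human - pred) ** 2) / ss_tot)
        out["logistic_params"] = tuple(float(p) for p in popt)
    return out


def noise_ceiling(human_values_per_observer) -> dict:
    """Predict each observer's normalized responses from the mean of all
    other observers' normalized responses (leave-one-out)."""
    obs = {k: normalize_unit_range(np.asarray(v, dtype=np.float64))
           for k, v in dict(human_values_per_observer).items()}
    if len(obs) < 3:
        raise ValueError("noise ceiling needs at least 3 observers")
    keys = list(obs)
    stack = np.stack([obs[k] for k in keys])
    rmse, corr = {}, {}
    for i, k in enumerate(keys):
        others = np.delete(stack, i, axis=0).mean(axis=0)
        rmse[k] = float(np.sqrt(np.mean((stack[i] - others) ** 2)))
        corr[k] = (float(np.corrcoef(stack[i], others)[0, 1])
                   if stack[i].std() > 0 and others.std() > 0 else np.nan)
    vals = [v for v in corr.values() if np.isfinite(v)]
    return {"rmse_per_observer": rmse, "correlation_per_observer": corr,
            "mean_rmse": float(np.mean(list(rmse.values()))),
            "mean_correlation": float(np.mean(vals)) if vals else np.nan}


# ---------------------------------------------------------------------------
# synthetic observers
# ---------------------------------------------------------------------------

def default_observer_population(n_observers: int = 20, seed: int = 0):
    """Observer parameter draws: beta log-normal (median 2, 0.3 log10 units
    sd), lapse uniform on [0, 0.1], jittered rating criteria."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    out = []
    for i in range(n_observers):
        beta = float(10 ** (np.log10(2.0) + 0.3 * rng.standard_normal()))
        lapse = float(rng.uniform(0, 0.1))
        base = np.linspace(-1.0, 1.0, 5) + rng.normal(0, 0.05, 5)
        base = np.sort(base)
        out.append(ObserverParams(beta=beta, lapse=lapse, criteria=tuple(base),
                                  rating_noise_sd=float(rng.uniform(0.2, 0.4)),
                                  seed=int(rng.integers(0, 2**31 - 1))))
    return out


def synthetic_observer(true_gloss, params: ObserverParams, design: str,
                       repetitions: int = 8, observer_id: int = 0,
                       pairs=None):
    """Simulate one observer.

    ``design='rating'``: for each stimulus and repetition, an internal value
    (standardized gloss + Gaussian noise) is cut by the 5 ordered criteria
    into a 1-6 rating; returns a RatingDataset.
    ``design='choice'``: for each (i, j) pair (all pairs by default),
    P(choose i) = lapse/2 + (1-lapse) * logistic(beta * (g_i - g_j)); returns
    a ChoiceDataset with `repetitions` trials per pair.
    """
    g = np.asarray(true_gloss, dtype=np.float64)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 31]))
    if design == "rating":
        z = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        rows = []
        for rep in range(repetitions):
            noisy = z + rng.normal(0, params.rating_noise_sd, len(z))
            ratings = 1 + np.searchsorted(np.asarray(params.criteria), noisy)
            for img, rat in enumerate(ratings):
                rows.append({"observer": observer_id, "image": img,
                             "repetition": rep, "rating": int(rat)})
        return RatingDataset(pd.DataFrame(rows))
    if design != "choice":
        raise ValueError("design must be 'rating' or 'choice'")
    if pairs is None:
        pairs = list(itertools.combinations(range(len(g)), 2))
    rows = []
    for pid, (i, j) in enumerate(pairs):
        delta = g[i] - g[j]
        if np.isinf(params.beta):
            p = 0.5 if delta == 0 else (1.0 if delta > 0 else 0.0)
        else:
            p = 1.0 / (1.0 + np.exp(-params.beta * delta))
        p = params.lapse / 2.0 + (1.0 - params.lapse) * p
        n_a = int(rng.binomial(repetitions, p))
        rows.append({"observer": observer_id, "pair": pid, "a": i, "b": j,
                     "n_a": n_a, "n_b": repetitions - n_a})
    return ChoiceDataset(pd.DataFrame(rows))


def fit_observer_params(choices: ChoiceDataset, true_gloss,
                        fix_lapse: float | None = None) -> ObserverParams:
    """Maximum-likelihood fit of (beta, lapse) under the choice model."""
    g = np.asarray(true_gloss, dtype=np.float64)
    t = choices.table
    if len(t) == 0 or (t["n_a"] + t["n_b"]).sum() == 0:
        raise ValueError("no trials to fit")
    deltas = g[t["a"].to_numpy()] - g[t["b"].to_numpy()]
    n_a = t["n_a"].to_numpy(dtype=float)
    n_b = t["n_b"].to_numpy(dtype=float)

    def nll(theta):
        beta = theta[0]
        lapse = fix_lapse if fix_lapse is not None else theta[1]
        p = 1.0 / (1.0 + np.exp(-beta * deltas))
        p = lapse / 2.0 + (1.0 - lapse) * p
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(n_a * np.log(p) + n_b * np.log(1 - p))

    if fix_lapse is not None:
        res = optimize.minimize_scalar(lambda b: nll([b]), bounds=(0.0, 100.0),
                                       method="bounded")
        if not res.success:
            raise RuntimeError("observer fit did not converge")
        return ObserverParams(beta=float(res.x), lapse=float(fix_lapse))
    best = None
    for b0, l0 in itertools.product((0.5, 2.0, 8.0), (0.01, 0.05)):
        res = optimize.minimize(nll, x0=np.array([b0, l0]),
                                bounds=[(0.0, 100.0), (0.0, 0.2)],
                                method="L-BFGS-B")
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("observer fit did not converge")
    return ObserverParams(beta=float(best.x[0]), lapse=float(best.x[1]))
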