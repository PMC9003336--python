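"""Evaluation harness: leave-one-out protocol, split optimisation, and the
time-horizon / sensor-count / simulated-dropout sweeps.

Protocol per fold (modular method, MM): the remaining trials are divided
into participant- and activity-balanced halves — a Classifier Training Set
(per-sensor 1-NN models) and a Probability Learning Set (per-sensor
confusion matrices).  The split is re-drawn ``n_repeats`` times and the
candidate with the highest mean per-sensor balanced accuracy is kept.  The
held-out trial is then classified by every sensor and the decisions fused.
The non-modular method (NMM) trains a single combined 1-NN on the whole
pool with no split.

Implementation note: every classifier here is a 1-NN under a fixed
fractional Minkowski metric, so all pairwise distance terms can be
computed once per horizon and every fold/split/combination evaluated by
slicing.  The combined classifier's distance decomposes additively over
per-sensor feature blocks, which also makes zero-filled dropout a
precomputable column sum.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from . import fusion as fus
from .classifiers import NeighbourModel, modal_label
from .conditioning import FilterSpec, WindowSpec, condition_trial
from .features import FeatureConfig, FeatureMatrix, assemble_feature_matrix
from .synthetic_data import Dataset, RawTrial, SensorSpec

__all__ = [
    "SplitPlan",
    "SweepResult",
    "SpearmanResult",
    "RatioResult",
    "Harness",
    "loocv_folds",
    "balanced_split",
    "confidence_interval",
    "spearman_rho",
    "time_sweep",
    "sensor_count_sweep",
    "dropout_sweep",
]

logger = logging.getLogger(__name__)

_DOM_SPLIT = 11
_DOM_COMBO = 12
_DOM_DROP = 13


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SplitPlan:
    fold: int
    testing_id: int
    classifier_training: tuple[int, ...]
    probability_learning: tuple[int, ...]
    seed: int | None = None
    training_pool: tuple[int, ...] = ()


@dataclass
class SweepResult:
    """Accuracy series over one swept variable for one method."""

    variable: str
    method: str
    values: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: np.ndarray
    seed: int | None = None


@dataclass
class SpearmanResult:
    rho: float
    n: int


@dataclass
class RatioResult:
    """Pointwise MM/NMM accuracy ratios over the swept variable."""

    values: np.ndarray
    ratios: np.ndarray
    minimum: float = field(init=False)
    maximum: float = field(init=False)
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        self.minimum = float(np.min(r))
        self.maximum = float(np.max(r))
        self.mean = float(np.mean(r))


# ---------------------------------------------------------------------------
# protocol primitives


def loocv_folds(n_trials: int) -> list[SplitPlan]:
    """One fold per trial; each fold's training pool is all other trials."""
    if n_trials < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    return [
        SplitPlan(
            fold=i,
            testing_id=i,
            classifier_training=(),
            probability_learning=(),
            training_pool=tuple(j for j in range(n_trials) if j != i),
        )
        for i in range(n_trials)
    ]


def balanced_split(
    ids: np.ndarray,
    participants: np.ndarray,
    activities: np.ndarray,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Split a trial pool into two halves balanced by participant and
    activity: within every (participant, activity) stratum the replicate
    trials are shuffled and dealt half-and-half (odd strata place their
    extra trial in a randomly chosen half, so imbalance is at most 1)."""
    ids = np.asarray(ids)
    if ids.size == 0:
        raise ValueError("training pool is empty")
    strata: dict[tuple, list[int]] = {}
    for i, tid in enumerate(ids):
        strata.setdefault((int(participants[i]), int(activities[i])), []).append(int(tid))
    first: list[int] = []
    second: list[int] = []
    for key in sorted(strata):
        members = np.array(strata[key])
        perm = rng.permutation(members.size)
        members = members[perm]
        half = members.size // 2
        if members.size % 2 == 1 and rng.random() < 0.5:
            half += 1
        first.extend(members[:half].tolist())
        second.extend(members[half:].tolist())
    # tiny pools of singleton strata can leave one half empty; both halves
    # must be usable (one trains models, the other estimates accuracies)
    if not first and len(second) > 1:
        first.append(second.pop())
    if not second and len(first) > 1:
        second.append(first.pop())
    return tuple(sorted(first)), tuple(sorted(second))


def confidence_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t-interval for the mean of ``values``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for an interval")
    if np.all(v == v[0]):  # degenerate sample: exactly zero-width interval
        return float(v[0]), float(v[0])
    m = v.mean()
    se = v.std(ddof=1) / math.sqrt(v.size)
    tq = sstats.t.ppf(0.5 + level / 2.0, df=v.size - 1)
    return float(m - tq * se), float(m + tq * se)


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties sharing the mean of their positions."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> SpearmanResult:
    """Spearman rank correlation with average-rank tie handling (the
    classical 1 - 6*sum(d^2)/(n(n^2-1)) form when no ties are present)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    denom = math.sqrt(float((dx**2).sum() * (dy**2).sum()))
    if denom == 0.0:
        return SpearmanResult(rho=0.0, n=x.size)
    return SpearmanResult(rho=float((dx * dy).sum() / denom), n=x.size)


# ---------------------------------------------------------------------------
# per-horizon engine


class _Engine:
    """Precomputed distance structure for one classification horizon."""

    def __init__(
        self,
        trials: list[RawTrial],
        sensors: list[SensorSpec],
        horizon: float,
        feature_config: FeatureConfig,
        window_spec: WindowSpec,
        distance_exponent: float,
    ) -> None:
        self.sensors = sensors
        self.horizon = horizon
        self.exponent = distance_exponent
        matrices, meta = assemble_feature_matrix(
            trials, sensors, horizon, feature_config,
            WindowSpec(window_spec.length, window_spec.step, horizon),
        )
        self.matrices = matrices
        self.meta = meta
        self.y = meta["category"].astype(int)
        self.classes = tuple(sorted(np.unique(self.y).tolist()))
        self.n = self.y.size
        p = distance_exponent

        # Window-level (sEMG) or trial-level (IMU) pairwise |dx|^p sums for
        # the per-sensor models, plus trial-level block sums for the
        # combined classifier (distance decomposes additively over blocks).
        self.win: dict[str, np.ndarray] = {}
        self.n_windows: dict[str, int] = {}
        blocks = []
        zeros = []
        for s in sensors:
            fm = matrices[s.sensor_id]
            x = fm.values.astype(np.float64)
            # Feature-by-feature accumulation avoids a (rows, rows, feats)
            # temporary; |dx|^0.5 is sqrt, the common fast path.
            d = np.zeros((x.shape[0], x.shape[0]), dtype=np.float64)
            for f in range(x.shape[1]):
                diff = np.abs(x[:, f][:, None] - x[:, f][None, :])
                d += np.sqrt(diff) if p == 0.5 else diff**p
            d = d.astype(np.float32)
            if fm.modality == "semg":
                w = int(fm.window_index.max()) + 1 if fm.window_index.size else 0
                self.win[s.sensor_id] = d
                self.n_windows[s.sensor_id] = w
                # Aligned-window trial block: sum_w d[(i,w),(j,w)].
                b = np.zeros((self.n, self.n), dtype=np.float64)
                for wi in range(w):
                    b += d[wi::w, wi::w]
                blocks.append(b)
                zeros.append((np.abs(x) ** p).sum(axis=1).reshape(self.n, w).sum(axis=1))
            else:
                self.win[s.sensor_id] = d.astype(np.float32)
                self.n_windows[s.sensor_id] = 0
                blocks.append(d.astype(np.float64))
                zeros.append((np.abs(x) ** p).sum(axis=1))
        self.blocks = np.stack(blocks)           # (S, n, n)
        self.zero_terms = np.stack(zeros)        # (S, n)

        self._mm_cache: dict[tuple[int, int], dict] = {}

    # -- per-sensor 1-NN predictions from the precomputed tables ----------

    def predict_sensor(self, sensor_idx: int, tests: np.ndarray, trains: np.ndarray) -> np.ndarray:
        """Trial-level predictions of one sensor's model for ``tests``,
        trained on ``trains`` (arrays of trial indices)."""
        s = self.sensors[sensor_idx]
        d = self.win[s.sensor_id]
        if s.modality == "imu":
            sub = d[np.ix_(tests, trains)]
            return self.y[trains[np.argmin(sub, axis=1)]]
        w = self.n_windows[s.sensor_id]
        rows = (tests[:, None] * w + np.arange(w)[None, :]).ravel()
        cols = (trains[:, None] * w + np.arange(w)[None, :]).ravel()
        sub = d[np.ix_(rows, cols)]
        nn = np.argmin(sub, axis=1)
        win_labels = self.y[trains[nn // w]].reshape(tests.size, w)
        return np.array([modal_label(win_labels[i]) for i in range(tests.size)])

    # -- MM fold cache -----------------------------------------------------

    def mm_fold(self, fold: int, cand: int, seed: int, n_repeats: int) -> dict:
        """Per-(fold, candidate-split) cache: the split, each sensor's
        confusion matrix (log-probabilities), balanced accuracy, and its
        prediction for the held-out trial."""
        key = (fold, cand)
        if key in self._mm_cache:
            return self._mm_cache[key]
        pool = np.array([j for j in range(self.n) if j != fold])
        rng = np.random.default_rng(np.random.SeedSequence((seed, _DOM_SPLIT, fold, cand)))
        part = self.meta["participant"][pool]
        act = self.meta["activity"][pool]
        ct, pl = balanced_split(pool, part, act, rng)
        ct_a, pl_a = np.array(ct, dtype=int), np.array(pl, dtype=int)
        n_s = len(self.sensors)
        c = len(self.classes)
        acc = np.empty(n_s)
        logp = np.empty((n_s, c, c))
        preds = np.empty(n_s, dtype=int)
        cms = []
        truth = self.y[pl_a]
        for si in range(n_s):
            pl_pred = self.predict_sensor(si, pl_a, ct_a)
            cm = fus.estimate_confusion(
                pl_pred.tolist(), truth.tolist(), self.classes,
                smoothing=1.0, sensor_id=self.sensors[si].sensor_id,
            )
            acc[si] = fus.sensor_accuracy(cm)
            logp[si] = np.log(cm.probs)
            preds[si] = int(self.predict_sensor(si, np.array([fold]), ct_a)[0])
            cms.append(cm)
        entry = {
            "split": SplitPlan(fold, fold, ct, pl, seed, tuple(pool.tolist())),
            "acc": acc,
            "logp": logp,
            "preds": preds,
            "cms": cms,
        }
        self._mm_cache[key] = entry
        return entry

    def mm_contributions(self, seed: int, n_repeats: int) -> tuple[np.ndarray, np.ndarray]:
        """For every (fold, candidate, sensor): the log-likelihood column
        selected by that sensor's test prediction, shape (F, R, S, C), and
        the per-sensor balanced accuracies, shape (F, R, S)."""
        c = len(self.classes)
        n_s = len(self.sensors)
        contrib = np.empty((self.n, n_repeats, n_s, c))
        accs = np.empty((self.n, n_repeats, n_s))
        for f in range(self.n):
            for r in range(n_repeats):
                e = self.mm_fold(f, r, seed, n_repeats)
                accs[f, r] = e["acc"]
                for si in range(n_s):
                    contrib[f, r, si] = e["logp"][si][:, e["preds"][si]]
        return contrib, accs

    # -- NMM ---------------------------------------------------------------

    def nmm_accuracy(self, active: np.ndarray, dropped: np.ndarray | None = None) -> float:
        """Combined-classifier LOOCV accuracy; ``dropped`` sensors (if any)
        contribute zero-filled query features against intact training
        features."""
        d = self.blocks[active].sum(axis=0)
        if dropped is not None and dropped.size:
            d = d + self.zero_terms[dropped].sum(axis=0)[None, :]
        d = d.copy()
        np.fill_diagonal(d, np.inf)
        pred = self.y[np.argmin(d, axis=1)]
        return float(np.mean(pred == self.y))


# ---------------------------------------------------------------------------
# harness


class Harness:
    """Caches conditioned trials and per-horizon engines for a dataset."""

    def __init__(
        self,
        dataset: Dataset,
        filter_spec: FilterSpec = FilterSpec(),
        window_spec: WindowSpec = WindowSpec(),
        feature_config: FeatureConfig = FeatureConfig(),
        n_repeats: int = 5,
        distance_exponent: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.dataset = dataset
        self.window_spec = window_spec
        self.feature_config = feature_config
        self.n_repeats = n_repeats
        self.exponent = distance_exponent
        self.seed = seed
        self.conditioned = [
            condition_trial(tr, dataset.sensors, filter_spec) for tr in dataset.trials
        ]
        self._engines: dict[float, _Engine] = {}
        self._mm_tables: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def engine(self, horizon: float) -> _Engine:
        if horizon not in self._engines:
            self._engines[horizon] = _Engine(
                self.conditioned, self.dataset.sensors, horizon,
                self.feature_config, self.window_spec, self.exponent,
            )
        return self._engines[horizon]

    def _tables(self, horizon: float) -> tuple[np.ndarray, np.ndarray]:
        if horizon not in self._mm_tables:
            self._mm_tables[horizon] = self.engine(horizon).mm_contributions(
                self.seed, self.n_repeats
            )
        return self._mm_tables[horizon]

    # -- public protocol ops ----------------------------------------------

    def optimise_split(self, fold: int, horizon: float, active: np.ndarray | None = None):
        """Choose the best of ``n_repeats`` candidate splits for one fold
        (highest mean per-sensor balanced accuracy over the active set;
        ties -> lowest repeat index).  Returns (SplitPlan, model bank,
        confusion matrices)."""
        eng = self.engine(horizon)
        if active is None:
            active = np.arange(len(eng.sensors))
        entries = [eng.mm_fold(fold, r, self.seed, self.n_repeats) for r in range(self.n_repeats)]
        scores = [e["acc"][active].mean() for e in entries]
        best = int(np.argmax(scores))
        e = entries[best]
        bank = self._model_bank(eng, np.array(e["split"].classifier_training))
        cms = {eng.sensors[si].sensor_id: e["cms"][si] for si in active}
        return e["split"], bank, cms

    def _model_bank(self, eng: _Engine, train_ids: np.ndarray) -> dict[str, NeighbourModel]:
        bank = {}
        for s in eng.sensors:
            fm: FeatureMatrix = eng.matrices[s.sensor_id]
            mask = np.isin(fm.trial_index, train_ids)
            bank[s.sensor_id] = NeighbourModel(
                fm.values[mask],
                eng.y[fm.trial_index[mask]],
                distance_exponent=self.exponent,
                row_ids=np.arange(fm.values.shape[0])[mask],
            )
        return bank

    def run_fold(
        self, fold: int, method: str, horizon: float, active_sensors=None
    ) -> bool:
        """Classify one held-out trial; True when the decision matches the
        trial's category.  ``active_sensors`` lists surviving sensor ids
        (dropout: MM excludes the rest from fusion, NMM zero-fills their
        feature columns)."""
        eng = self.engine(horizon)
        ids = [s.sensor_id for s in eng.sensors]
        if active_sensors is None:
            active = np.arange(len(ids))
        else:
            active = np.array([ids.index(sid) for sid in active_sensors])
        if method == "mm":
            split, bank, cms = self.optimise_split(fold, horizon, np.arange(len(ids)))
            preds = {}
            for si in active:
                sid = ids[si]
                fm = eng.matrices[sid]
                mask = fm.trial_index == fold
                model = bank[sid]
                wf = fm.values[mask]
                preds[sid] = modal_label(model.predict(wf))
            r = fus.fuse(preds, cms, fus.ClassPrior.uniform(eng.classes))
            return bool(r.decision == eng.y[fold])
        if method == "nmm":
            dropped = np.array(
                [i for i in range(len(ids)) if i not in set(active.tolist())], dtype=int
            )
            d = eng.blocks[:, fold, :].copy()  # (S, n)
            keep = np.ones(len(ids), bool)
            keep[dropped] = False
            tot = d[keep].sum(axis=0)
            if dropped.size:
                tot = tot + eng.zero_terms[dropped].sum(axis=0)
            tot[fold] = np.inf
            pred = eng.y[int(np.argmin(tot))]
            return bool(pred == eng.y[fold])
        raise ValueError(f"unknown method {method!r}")

    # -- accuracies over all folds ----------------------------------------

    def mm_accuracy(self, horizon: float, active: np.ndarray,
                    select_over: np.ndarray | None = None) -> float:
        """MM LOOCV accuracy with sensor subset ``active``; candidate
        splits are selected by mean accuracy over ``select_over`` (default:
        the active set itself, i.e. the network was trained knowing its
        sensors)."""
        contrib, accs = self._tables(horizon)
        eng = self.engine(horizon)
        if select_over is None:
            select_over = active
        if select_over.size:
            cand = np.argmax(accs[:, :, select_over].mean(axis=2), axis=1)
        else:
            cand = np.zeros(eng.n, dtype=int)
        c = len(eng.classes)
        log_prior = np.full(c, -math.log(c))
        if active.size:
            picked = contrib[np.arange(eng.n), cand][:, active, :]  # (F, |A|, C)
            scores = log_prior[None, :] + picked.sum(axis=1)
        else:
            scores = np.tile(log_prior, (eng.n, 1))
        pred = np.array(eng.classes)[np.argmax(scores, axis=1)]
        return float(np.mean(pred == eng.y))

    def nmm_accuracy(self, horizon: float, active: np.ndarray,
                     dropped: np.ndarray | None = None) -> float:
        return self.engine(horizon).nmm_accuracy(active, dropped)


# ---------------------------------------------------------------------------
# sweeps


def _sample_combinations(
    n_sensors: int, r: int, n_combos: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    total = math.comb(n_sensors, r)
    if total <= n_combos:
        if total < n_combos:
            logger.info(
                "only %d distinct combinations of size %d exist; using all", total, r
            )
        return [tuple(c) for c in itertools.combinations(range(n_sensors), r)]
    seen: set[tuple[int, ...]] = set()
    while len(seen) < n_combos:
        seen.add(tuple(sorted(rng.choice(n_sensors, size=r, replace=False).tolist())))
    return sorted(seen)


def time_sweep(
    harness: Harness,
    horizons=None,
    methods: tuple[str, ...] = ("mm", "nmm"),
) -> tuple[dict[str, SweepResult], dict[str, SpearmanResult]]:
    """Accuracy of each method against the classification horizon with all
    sensors active, plus the Spearman trend statistic per method."""
    if horizons is None:
        horizons = np.arange(200.0, harness.window_spec.horizon + 1, 50.0)
    horizons = np.asarray(horizons, dtype=float)
    duration = harness.dataset.design.trial_duration
    if np.any(horizons > duration):
        raise ValueError("horizon exceeds trial duration")
    n_s = len(harness.dataset.sensors)
    all_sensors = np.arange(n_s)
    acc = {m: [] for m in methods}
    for h in horizons:
        for m in methods:
            if m == "mm":
                acc[m].append(harness.mm_accuracy(h, all_sensors))
            else:
                acc[m].append(harness.nmm_accuracy(h, all_sensors))
    results = {}
    trends = {}
    for m in methods:
        a = np.array(acc[m])
        results[m] = SweepResult(
            variable="horizon_ms", method=m, values=horizons,
            mean=a, lower=a.copy(), upper=a.copy(),
            n=np.ones(horizons.size, dtype=int), seed=harness.seed,
        )
        trends[m] = spearman_rho(a, horizons)
    return results, trends


def sensor_count_sweep(
    harness: Harness,
    r_values=None,
    n_combos: int = 10,
    horizon: float | None = None,
    seed: int | None = None,
) -> tuple[dict[str, SweepResult], RatioResult]:
    """Accuracy of both methods as the network size R grows, each point
    averaged over random sensor combinations (methods trained per
    combination; no dropout)."""
    n_s = len(harness.dataset.sensors)
    if r_values is None:
        r_values = np.arange(1, n_s + 1)
    r_values = np.asarray(r_values, dtype=int)
    if np.any(r_values > n_s) or np.any(r_values < 1):
        raise ValueError("R must lie in 1..n_sensors")
    if n_combos < 1:
        raise ValueError("n_combos must be >= 1")
    if horizon is None:
        horizon = harness.window_spec.horizon
    if seed is None:
        seed = harness.seed
    out = {m: {"mean": [], "lo": [], "hi": [], "n": []} for m in ("mm", "nmm")}
    ratios = []
    for r in r_values:
        rng = np.random.default_rng(np.random.SeedSequence((seed, _DOM_COMBO, int(r))))
        combos = _sample_combinations(n_s, int(r), n_combos, rng)
        mm = np.array([harness.mm_accuracy(horizon, np.array(c)) for c in combos])
        nmm = np.array([harness.nmm_accuracy(horizon, np.array(c)) for c in combos])
        for m, a in (("mm", mm), ("nmm", nmm)):
            out[m]["mean"].append(a.mean())
            if a.size >= 2:
                lo, hi = confidence_interval(a)
            else:
                lo = hi = a.mean()
            out[m]["lo"].append(lo)
            out[m]["hi"].append(hi)
            out[m]["n"].append(a.size)
        ratios.append(mm.mean() / nmm.mean() if nmm.mean() > 0 else np.nan)
    results = {
        m: SweepResult(
            variable="n_sensors", method=m, values=r_values.astype(float),
            mean=np.array(out[m]["mean"]), lower=np.array(out[m]["lo"]),
            upper=np.array(out[m]["hi"]), n=np.array(out[m]["n"]), seed=seed,
        )
        for m in ("mm", "nmm")
    }
    return results, RatioResult(values=r_values.astype(float), ratios=np.array(ratios))


def dropout_sweep(
    harness: Harness,
    n_values=None,
    n_combos: int = 10,
    n_repetitions: int = 5,
    horizon: float | None = None,
    seed: int | None = None,
) -> tuple[dict[str, SweepResult], RatioResult]:
    """Robustness to sensors dropping out of a network trained once with
    every sensor present.

    For each count N of dropped sensors, random dropped sets are drawn;
    the MM excludes them from fusion (reusing the confusion matrices
    learned with all sensors — no re-estimation), the NMM zero-fills their
    feature columns.  Intervals are over repetition means.
    """
    n_s = len(harness.dataset.sensors)
    if n_values is None:
        n_values = np.arange(0, n_s)
    n_values = np.asarray(n_values, dtype=int)
    if np.any(n_values >= n_s) or np.any(n_values < 0):
        raise ValueError("N must lie in 0..n_sensors-1")
    if horizon is None:
        horizon = harness.window_spec.horizon
    if seed is None:
        seed = harness.seed
    all_sensors = np.arange(n_s)
    out = {m: {"mean": [], "lo": [], "hi": [], "n": []} for m in ("mm", "nmm")}
    ratios = []
    for nv in n_values:
        rep_means = {"mm": [], "nmm": []}
        for rep in range(n_repetitions):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, _DOM_DROP, int(nv), rep))
            )
            mm_accs, nmm_accs = [], []
            for _ in range(n_combos):
                dropped = np.sort(rng.choice(n_s, size=int(nv), replace=False))
                active = np.setdiff1d(all_sensors, dropped)
                mm_accs.append(
                    harness.mm_accuracy(horizon, active, select_over=all_sensors)
                )
                nmm_accs.append(harness.nmm_accuracy(horizon, active, dropped))
            rep_means["mm"].append(float(np.mean(mm_accs)))
            rep_means["nmm"].append(float(np.mean(nmm_accs)))
        for m in ("mm", "nmm"):
            a = np.array(rep_means[m])
            out[m]["mean"].append(a.mean())
            if a.size >= 2:
                lo, hi = confidence_interval(a)
            else:
                lo = hi = a.mean()
            out[m]["lo"].append(lo)
            out[m]["hi"].append(hi)
            out[m]["n"].append(a.size)
        mm_m, nmm_m = np.mean(rep_means["mm"]), np.mean(rep_means["nmm"])
        ratios.append(mm_m / nmm_m if nmm_m > 0 else np.nan)
    results = {
        m: SweepResult(
            variable="n_dropped", method=m, values=n_values.astype(float),
            mean=np.array(out[m]["mean"]), lower=np.array(out[m]["lo"]),
            upper=np.array(out[m]["hi"]), n=np.array(out[m]["n"]), seed=seed,
        )
        for m in ("mm", "nmm")
    }
    return results, RatioResult(values=n_values.astype(float), ratios=np.array(ratios))
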