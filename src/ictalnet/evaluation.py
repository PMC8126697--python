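"""Detection metrics and the seed-based leave-one-patient-out protocols.

Detection is scored by the area under the precision-recall curve (step-curve
integration, robust under class imbalance); onset regression by mean
absolute error and the fraction of onsets recovered within a +/-5 s
tolerance.  Two personalization scenarios are supported: seed epochs drawn
uniformly at random from the held-out patient's history, or that patient's
chronologically earliest consecutive ictal epochs (the new-implant setting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InfeasibleError, ValidationError
from .io import RecordingMetadata
from .network import NetworkSpec, build_network, forward_many
from .synthetic import Cohort, PatientData
from .training import Example, TrainConfig, train
from .augment import AugmentConfig

SCENARIOS = ("random", "earliest_consecutive")
DEFAULT_SEED_SIZES = (0, 5, 10, 15, 20, 25, 30)
ONSET_TOLERANCE_S = 5.0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def auprc(labels, scores) -> float:
    """Area under the precision-recall step curve.

    Thresholds sweep the distinct scores in descending order (ties collapse
    into a single threshold); the area accumulates precision at each recall
    increment, which equals exhaustive threshold enumeration on small inputs.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1 or y.size == 0:
        raise ValidationError("labels and scores must be equal-length 1-D sequences")
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValidationError("auprc requires at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied score block (single threshold)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y.size - 1]
    tp, fp = tp[idx], fp[idx]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def _extract_t(annotations) -> np.ndarray:
    out = []
    for a in annotations:
        if getattr(a, "s", 1) != 1:
            raise ValidationError("regression metrics require ictal (s=1) annotations")
        out.append(float(a.t if hasattr(a, "t") else a))
    return np.array(out)


def _extract_t_hat(predictions) -> np.ndarray:
    return np.array(
        [float(p.t_hat) if hasattr(p, "t_hat") else float(p) for p in predictions]
    )


def onset_mae(annotations, predictions) -> float:
    """Mean absolute onset error in seconds over ictal epochs."""
    t = _extract_t(annotations)
    if t.size == 0:
        raise ValidationError("onset_mae requires at least one ictal epoch")
    t_hat = _extract_t_hat(predictions)
    if t_hat.shape != t.shape:
        raise ValidationError("annotation/prediction length mismatch")
    return float(np.mean(np.abs(t_hat - t)))


def tolerance_accuracy(annotations, predictions, tol: float = ONSET_TOLERANCE_S) -> float:
    """Fraction of ictal epochs with ``|t_hat - t| < tol`` (strict)."""
    t = _extract_t(annotations)
    if t.size == 0:
        raise ValidationError("tolerance_accuracy requires at least one ictal epoch")
    t_hat = _extract_t_hat(predictions)
    return float(np.mean(np.abs(t_hat - t) < tol))


def kruskal_wallis_by_site(results, site_map: dict) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H over per-patient AUPRCs grouped by
    implant site, with the chi-squared p-value."""
    groups: dict[str, list[float]] = {}
    for r in results:
        site = site_map.get(r.patient_id)
        if site is None:
            continue
        groups.setdefault(site, []).append(r.auprc)
    groups = {k: v for k, v in groups.items() if v}
    if len(groups) < 2:
        raise ValidationError("need at least 2 implant-site groups with observations")
    values = list(groups.values())
    concat = np.concatenate(values)
    if np.all(concat == concat[0]):
        # scipy raises when all observations are identical; H is 0 by definition
        return 0.0, 1.0
    h, p = sstats.kruskal(*values)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Seed selection and inclusion filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedSet:
    """Personalization epochs for one held-out patient."""

    patient_id: str
    ictal_ids: tuple[int, ...]
    nonictal_ids: tuple[int, ...]
    scenario: str

    def __post_init__(self) -> None:
        if len(self.ictal_ids) != len(self.nonictal_ids):
            raise ValidationError("seed set must pair ictal and non-ictal equally")
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")

    @property
    def ids(self) -> frozenset[int]:
        return frozenset(self.ictal_ids) | frozenset(self.nonictal_ids)


def select_seed(
    patient_epochs: PatientData,
    n: int,
    scenario: str,
    rng: np.random.Generator,
) -> SeedSet:
    """Choose ``n`` ictal seed epochs plus ``n`` paired scheduled non-ictal
    epochs from one patient.

    ``random``: uniform without replacement.  ``earliest_consecutive``: the
    ``n`` chronologically first ictal epochs.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    epochs = patient_epochs.epochs
    pid = patient_epochs.profile.patient_id
    ictal = [i for i, (_, ann) in enumerate(epochs) if ann.s == 1]
    scheduled = [
        i
        for i, (ep, ann) in enumerate(epochs)
        if ann.s == 0 and ep.trigger == "scheduled"
    ]
    if len(ictal) < n:
        raise InfeasibleError(
            f"patient {pid}: {len(ictal)} ictal epochs available, {n} requested"
        )
    if len(scheduled) < n:
        raise InfeasibleError(
            f"patient {pid}: {len(scheduled)} scheduled non-ictal epochs "
            f"available, {n} required for pairing"
        )
    if n == 0:
        return SeedSet(pid, (), (), scenario)
    if scenario == "random":
        chosen = sorted(int(i) for i in rng.choice(ictal, size=n, replace=False))
    else:
        by_time = sorted(ictal, key=lambda i: epochs[i][0].recorded_at)
        chosen = by_time[:n]
    paired = sorted(int(i) for i in rng.choice(scheduled, size=n, replace=False))
    return SeedSet(pid, tuple(chosen), tuple(paired), scenario)


def inclusion_filter(
    records: list[RecordingMetadata], max_seed: int = 30
) -> list[str]:
    """Patients with strictly more than ``max_seed + 5`` ictal patterns."""
    return [r.patient_id for r in records if r.n_ictal_patterns > max_seed + 5]


# ---------------------------------------------------------------------------
# Leave-one-patient-out evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalResult:
    """One (held-out patient, seed size) evaluation cell."""

    patient_id: str
    seed_size: int
    auprc: float
    onset_mae: float
    tolerance_fraction: float
    n_test_epochs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auprc <= 1.0):
            raise ValidationError("auprc must be in [0, 1]")
        if self.onset_mae < 0:
            raise ValidationError("onset_mae must be >= 0")


@dataclass
class LopoOutcome:
    results: list  # list[EvalResult]
    missing: list  # list[dict] infeasible cells with diagnostics
    summary: dict  # per-seed-size mean/SD/CI
    scenario: str = "random"

    def to_dataframe(self, site_map: dict | None = None) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "patient": r.patient_id,
                    "site": (site_map or {}).get(r.patient_id, ""),
                    "scenario": self.scenario,
                    "seed_size": r.seed_size,
                    "auprc": r.auprc,
                    "onset_mae": r.onset_mae,
                    "tolerance_fraction": r.tolerance_fraction,
                    "n_test": r.n_test_epochs,
                }
            )
        return pd.DataFrame(rows)


def _examples_for_patient(pdata: PatientData, patient_index: int) -> list[Example]:
    out = []
    for epoch, ann in pdata.epochs:
        out.append(
            Example(
                samples=np.asarray(epoch.samples, dtype=np.float32),
                s=ann.s,
                t=float(ann.t) if ann.s == 1 else float("nan"),
                patient_index=patient_index,
            )
        )
    return out


def bootstrap_ci(
    values: np.ndarray,
    rng: np.random.Generator,
    n_resamples: int = 10_000,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the mean."""
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def summarize_results(
    results: list[EvalResult], rng: np.random.Generator
) -> dict:
    """Across-patient mean +/- SD and bootstrap 95% CI per seed size."""
    summary: dict = {}
    by_n: dict[int, list[EvalResult]] = {}
    for r in results:
        by_n.setdefault(r.seed_size, []).append(r)
    for n in sorted(by_n):
        cells = by_n[n]
        au = np.array([c.auprc for c in cells])
        mae = np.array([c.onset_mae for c in cells])
        ci = bootstrap_ci(au, rng)
        summary[n] = {
            "n_patients": len(cells),
            "auprc_mean": float(au.mean()),
            "auprc_sd": float(au.std(ddof=1)) if au.size > 1 else 0.0,
            "auprc_ci95": ci,
            "mae_mean": float(mae.mean()),
            "mae_sd": float(mae.std(ddof=1)) if mae.size > 1 else 0.0,
            "tolerance_mean": float(np.mean([c.tolerance_fraction for c in cells])),
        }
    return summary


def lopo_evaluate(
    dataset: Cohort,
    scenario: str = "random",
    seed_sizes: tuple[int, ...] = DEFAULT_SEED_SIZES,
    train_config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
    network_spec: NetworkSpec | None = None,
    augment_config: AugmentConfig | None = None,
) -> LopoOutcome:
    """Seed-based leave-one-patient-out evaluation.

    For every held-out patient passing the inclusion filter and every seed
    size: train a fresh network on all other patients' epochs plus the seed
    set (ictal + paired non-ictal), then evaluate on the held-out patient's
    remaining epochs.  Seed and test sets are disjoint by construction.
    """
    if dataset.n_patients < 2:
        raise ValidationError("leave-one-patient-out requires at least 2 patients")
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    train_config = train_config or TrainConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    base = int(rng.integers(0, 2**31 - 1))
    max_seed = max(seed_sizes)
    qualifying = set(inclusion_filter(dataset.metadata(), max_seed=max_seed))

    spec_template = network_spec or NetworkSpec()
    all_examples = [
        _examples_for_patient(p, i) for i, p in enumerate(dataset.patients)
    ]

    results: list[EvalResult] = []
    missing: list[dict] = []
    for held_idx, pdata in enumerate(dataset.patients):
        pid = pdata.profile.patient_id
        if pid not in qualifying:
            continue
        for n in seed_sizes:
            cell_rng = np.random.default_rng(
                np.random.SeedSequence([base, held_idx, n])
            )
            try:
                seed_set = select_seed(pdata, n, scenario, cell_rng)
            except InfeasibleError as exc:
                missing.append({"patient": pid, "seed_size": n, "reason": str(exc)})
                continue
            train_set: list[Example] = []
            for i, exs in enumerate(all_examples):
                if i != held_idx:
                    train_set.extend(exs)
            held_examples = all_examples[held_idx]
            for i in sorted(seed_set.ids):
                train_set.append(held_examples[i])
            test_ids = [
                i for i in range(len(held_examples)) if i not in seed_set.ids
            ]
            assert not set(test_ids) & set(seed_set.ids)

            spec = dc_replace(spec_template, n_patients=dataset.n_patients)
            net = build_network(spec, seed=int(cell_rng.integers(0, 2**31 - 1)))
            cfg = dc_replace(
                train_config, seed=int(cell_rng.integers(0, 2**31 - 1))
            )
            train(net, train_set, cfg, augment_config=augment_config)

            test_x = np.stack([held_examples[i].samples for i in test_ids])
            test_pidx = np.full(len(test_ids), held_idx)
            s_hat, t_hat = forward_many(net, test_x, test_pidx)
            labels = np.array([held_examples[i].s for i in test_ids])
            if labels.min() == labels.max():
                missing.append(
                    {
                        "patient": pid,
                        "seed_size": n,
                        "reason": "test set contains a single class",
                    }
                )
                continue
            cell_auprc = auprc(labels, s_hat)
            ict = labels == 1
            errs = np.abs(t_hat[ict] - np.array(
                [held_examples[i].t for i in test_ids]
            )[ict])
            results.append(
                EvalResult(
                    patient_id=pid,
                    seed_size=n,
                    auprc=cell_auprc,
                    onset_mae=float(errs.mean()),
                    tolerance_fraction=float(np.mean(errs < ONSET_TOLERANCE_S)),
                    n_test_epochs=len(test_ids),
                )
            )
    summary = summarize_results(
        results, np.random.default_rng(np.random.SeedSequence([base, 999]))
    )
    return LopoOutcome(
        results=results, missing=missing, summary=summary, scenario=scenario
    )
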