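"""End-to-end cross-site experiment orchestration.

The analytic flow: generate (or load) two site cohorts; split the source
cohort 7:3 by recruitment time into train/validation; reserve the earliest
ten target-site samples (label-stratified) for fine-tuning and the rest for
test; train the CNN on the (optionally augmented) training partition with
early stopping on validation AUC; optionally fine-tune on the reserved
target samples; evaluate on validation and test with a Youden threshold
frozen on validation scores.

Six conditions mirror a cross-site diagnostic study design: baseline,
fine-tuning only, SDA, NSA, and each augmentation plus fine-tuning, with an
optional site-reversed replication. One master seed fans out
deterministically (via ``numpy.random.SeedSequence``) to the generator,
augmentation, model and bootstrap seeds, so a run is reproducible
bit-for-bit. Partition bookkeeping is explicit and every evaluation checks
sample fingerprints: augmented samples can never enter validation/test, and
a fine-tune sample appearing in an evaluation set aborts the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import cnn
from .augmentation import AugmentationConfig, augment_dataset
from .cnn import FinetuneConfig, ModelConfig, TrainedModel
from .errors import InvalidArgumentError, LeakageError
from .evaluation import EvalReport, evaluate_condition, youden_threshold
from .preprocess import BreathprintImage, fit_normalization, traces_to_images
from .synthetic import default_class_model, default_site_model, simulate_cohort

CONDITIONS = ("baseline", "finetune_only", "SDA", "NSA", "SDA_finetune", "NSA_finetune")

DEFAULT_COHORTS = {"S1": (90, 16, 62), "S2": (28, 10, 25)}


@dataclass(frozen=True)
class SplitSpec:
    """Assignment of every sample id to exactly one partition."""

    assignments: dict  # sample_id -> "train"|"validation"|"test"|"finetune"
    source_site: str
    target_site: str
    ratio: float = 0.7

    def ids(self, partition: str) -> frozenset:
        return frozenset(s for s, p in self.assignments.items() if p == partition)


@dataclass
class ExperimentConfig:
    conditions: tuple = CONDITIONS
    cohort_sizes: dict = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    source_site: str = "S1"
    target_site: str = "S2"
    reverse_sites: bool = False
    effect_scale: float = 1.0
    trace_length: int = 256
    master_seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    nsa: AugmentationConfig = field(default_factory=lambda: AugmentationConfig(method="NSA"))
    sda: AugmentationConfig = field(default_factory=lambda: AugmentationConfig(method="SDA"))
    n_finetune: int = 10
    bootstrap_B: int = 1000
    alpha: float = 0.05

    def __post_init__(self):
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise InvalidArgumentError(f"unknown conditions {sorted(unknown)}")
        if not self.conditions:
            raise InvalidArgumentError("at least one condition is required")


def split_cohort(samples, ratio: float = 0.7) -> dict:
    """Temporal 7:3 split: earliest ceil(ratio*N) by recruitment time train.

    Purely deterministic; ties in recruitment time break by sample id. A
    168-sample cohort yields the 118/50 train/validation partition.
    """
    for s in samples:
        if s.recruitment_time is None:
            raise InvalidArgumentError(f"sample {s.sample_id!r} lacks a recruitment time")
    ordered = sorted(samples, key=lambda s: (s.recruitment_time, s.sample_id))
    n_train = math.ceil(ratio * len(ordered))
    return {
        s.sample_id: ("train" if i < n_train else "validation")
        for i, s in enumerate(ordered)
    }


def select_finetune_subset(target_samples, n: int = 10) -> dict:
    """Mark n target samples for fine-tuning, the rest for test.

    Selection is the earliest samples by recruitment time within each
    label stratum, with per-label counts allocated by largest remainder so
    the subset mirrors the target cohort's class mix — the way a
    prospective deployment would accumulate its first calibration samples.
    """
    if n > len(target_samples):
        raise InvalidArgumentError(f"n={n} exceeds target cohort size {len(target_samples)}")
    assignments = {s.sample_id: "test" for s in target_samples}
    if n == 0:
        return assignments
    by_label: dict[str, list] = {}
    for s in sorted(target_samples, key=lambda s: (s.recruitment_time, s.sample_id)):
        by_label.setdefault(s.label, []).append(s)
    total = len(target_samples)
    quotas = {lab: n * len(ss) / total for lab, ss in by_label.items()}
    counts = {lab: min(int(q), len(by_label[lab])) for lab, q in quotas.items()}
    # distribute the remainder by largest fractional part
    rema = sorted(quotas, key=lambda lab: quotas[lab] - int(quotas[lab]), reverse=True)
    i = 0
    while sum(counts.values()) < n:
        lab = rema[i % len(rema)]
        if counts[lab] < len(by_label[lab]):
            counts[lab] += 1
        i += 1
    for lab, c in counts.items():
        for s in by_label[lab][:c]:
            assignments[s.sample_id] = "finetune"
    return assignments


def _partition(images, assignments, name) -> list[BreathprintImage]:
    out = []
    for img in images:
        if assignments.get(img.sample_id) == name:
            img = replace(img, partition=name)
            out.append(img)
    return out


def _check_eval_leakage(model: TrainedModel, images, partition: str) -> None:
    ids = {img.sample_id for img in images}
    ft = model.provenance.get("finetune_ids", frozenset())
    tr = model.provenance.get("train_ids", frozenset())
    bad = ids & ft
    if bad:
        raise LeakageError(f"fine-tune samples in {partition} evaluation: {sorted(bad)}")
    bad = ids & tr if partition in ("validation", "test") else set()
    if bad:
        raise LeakageError(f"training samples in {partition} evaluation: {sorted(bad)}")
    for img in images:
        if img.augmented:
            raise LeakageError(f"augmented sample {img.sample_id!r} in {partition} evaluation")


def _evaluate(model, images, condition, eval_set, threshold, config, seed) -> EvalReport:
    _check_eval_leakage(model, images, eval_set)
    scores = cnn.predict_proba(model, images)
    labels = np.array([1.0 if img.is_cancer else 0.0 for img in images])
    report = evaluate_condition(
        f"{condition}/{eval_set}", labels, scores, threshold,
        B=config.bootstrap_B, alpha=config.alpha, seed=seed,
    )
    return report


def run_experiment(config: ExperimentConfig) -> list[EvalReport]:
    """Run every requested condition; one EvalReport per condition/eval set.

    The full grid produces seven reports (one validation row for the
    unaugmented baseline model plus six test rows), doubled when
    ``reverse_sites`` also runs the site-swapped replication.
    """
    reports = _run_direction(config, config.source_site, config.target_site, tag="")
    if config.reverse_sites:
        reports += _run_direction(config, config.target_site, config.source_site, tag="reversed:")
    return reports


def _run_direction(config: ExperimentConfig, source: str, target: str, tag: str) -> list[EvalReport]:
    ss = np.random.SeedSequence(config.master_seed)
    (seed_src, seed_tgt, seed_model, seed_nsa, seed_sda, seed_boot) = ss.spawn(6)
    boot_seed = int(np.random.default_rng(seed_boot).integers(0, 2**31 - 1))

    class_model = default_class_model(config.effect_scale)
    cohorts = {}
    for site, site_seed in ((config.source_site, seed_src), (config.target_site, seed_tgt)):
        nc, nh, nd = config.cohort_sizes[site]
        cohorts[site] = simulate_cohort(
            nc, nh, nd, site,
            class_model=class_model,
            site_model=default_site_model(site),
            T=config.trace_length,
            seed=site_seed,
        )
    source_traces, target_traces = cohorts[source], cohorts[target]

    assignments = split_cohort(source_traces, ratio=0.7)
    assignments.update(select_finetune_subset(target_traces, n=config.n_finetune))
    split = SplitSpec(assignments=assignments, source_site=source, target_site=target)

    # Normalization statistics come from raw training traces only.
    train_traces = [t for t in source_traces if assignments[t.sample_id] == "train"]
    stats = fit_normalization(train_traces)
    source_images = traces_to_images(source_traces, "per_channel_zscore", stats)
    target_images = traces_to_images(target_traces, "per_channel_zscore", stats)

    train_imgs = _partition(source_images, assignments, "train")
    val_imgs = _partition(source_images, assignments, "validation")
    test_imgs = _partition(target_images, assignments, "test")
    ft_imgs = _partition(target_images, assignments, "finetune")

    model_seed = int(np.random.default_rng(seed_model).integers(0, 2**31 - 1))
    model_cfg = replace(config.model, seed=model_seed,
                        finetune=replace(config.model.finetune, n_samples=config.n_finetune))

    def _train(images):
        return cnn.train(cnn.build_model(model_cfg), images, model_cfg, validation=val_imgs)

    needed = set(config.conditions)
    models: dict[str, TrainedModel] = {}
    if needed & {"baseline", "finetune_only"}:
        models["base"] = _train(train_imgs)
    if needed & {"SDA", "SDA_finetune"}:
        sda_cfg = replace(config.sda, seed=int(np.random.default_rng(seed_sda).integers(0, 2**31 - 1)))
        models["SDA"] = _train(augment_dataset(train_imgs, sda_cfg))
    if needed & {"NSA", "NSA_finetune"}:
        nsa_cfg = replace(config.nsa, seed=int(np.random.default_rng(seed_nsa).integers(0, 2**31 - 1)))
        models["NSA"] = _train(augment_dataset(train_imgs, nsa_cfg))

    def _threshold(model):
        scores = cnn.predict_proba(model, val_imgs)
        labels = np.array([1.0 if img.is_cancer else 0.0 for img in val_imgs])
        return youden_threshold(labels, scores)

    reports = []
    if "baseline" in needed:
        thr = _threshold(models["base"])
        reports.append(_evaluate(models["base"], val_imgs, tag + "baseline", "validation",
                                 thr, config, boot_seed))
        reports.append(_evaluate(models["base"], test_imgs, tag + "baseline", "test",
                                 thr, config, boot_seed))
    plan = {
        "finetune_only": ("base", True),
        "SDA": ("SDA", False),
        "NSA": ("NSA", False),
        "SDA_finetune": ("SDA", True),
        "NSA_finetune": ("NSA", True),
    }
    for cond in config.conditions:
        if cond == "baseline":
            continue
        base_name, do_ft = plan[cond]
        model = models[base_name]
        if do_ft:
            model = cnn.fine_tune(model, ft_imgs, model_cfg)
        reports.append(_evaluate(model, test_imgs, tag + cond, "test",
                                 _threshold(model), config, boot_seed))

    for r in reports:
        r.provenance = {
            "master_seed": config.master_seed,
            "source_site": source,
            "target_site": target,
            "n_train": len(train_imgs),
            "n_validation": len(val_imgs),
            "n_test": len(test_imgs),
            "n_finetune": len(ft_imgs),
        }
    return reports
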