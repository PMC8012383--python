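"""Train / identify orchestration: contours -> features -> PCA -> LDA -> AGNES.

``run_train`` fits the whole chain on labelled howls and reports the PC
variance table, LD proportions and training accuracies (both by the
discriminant classifier and by clustering the training LD scores).
``run_identify`` pushes a batch of howls — typically unknown — through the
same fitted equations, clusters them, counts the putative individuals, and
scores a confusion matrix when identities are supplied for validation.
Labels in the identify step are used for evaluation only, never for fitting.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contours import GRID_STEP, F0Contour, resample_contour
from .clustering import (
    ClusterAssignment,
    ConfusionMatrix,
    Dendrogram,
    agnes_cluster,
    calibrate_cut_height,
    count_individuals,
    cut_dendrogram,
    cut_to_k,
    evaluate_identification,
)
from .exceptions import HowlIdError
from .features import build_feature_table, duration_filter
from .lda import LDAModel, classify, fit_lda, project_ld
from .pca import PCAModel, fit_pca, project, select_components

logger = logging.getLogger(__name__)

#: Recommended batch-size ceiling for identification runs.
MAX_RECOMMENDED_BATCH = 100
#: Minimum/comfortable training howls per individual.
MIN_HOWLS_PER_INDIVIDUAL = 3
COMFORTABLE_HOWLS_PER_INDIVIDUAL = 5


@dataclass
class RunConfig:
    """All pipeline constants in one place.

    Defaults are the canonical analysis settings: 0.1 s resampling grid,
    howls strictly longer than 5 s, correlation-matrix PCA with the >5%
    variance-retention rule, two linear discriminants carried to
    clustering, Manhattan-metric average-linkage AGNES cut at a clustering
    scale of 2.2.
    """

    resample_step: float = GRID_STEP
    min_duration: float = 5.0
    scale_mode: str = "correlation"
    variance_threshold: float = 0.05
    n_lds: int = 2
    metric: str = "manhattan"
    linkage: str = "average"
    cut_height: float | None = None  # None: calibrate on the training dendrogram
    height_scale: str = "raw"
    n_clusters: int | None = None
    sd_mode: str = "sample"
    priors: str = "proportional"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("resample_step", "variance_threshold", "cut_height"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise HowlIdError(f"{name} must be non-negative")
        if self.resample_step <= 0:
            raise HowlIdError("resample_step must be positive")
        if self.n_lds < 1:
            raise HowlIdError("n_lds must be at least 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class TrainResult:
    pca_model: PCAModel
    lda_model: LDAModel
    feature_table: pd.DataFrame
    pc_scores: pd.DataFrame
    ld_scores: pd.DataFrame
    dendrogram: Dendrogram
    assignment: ClusterAssignment
    confusion: ConfusionMatrix
    cut_height: float
    report: dict = field(repr=False)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pca_model.save(outdir / "pca_model.json")
        self.lda_model.save(outdir / "lda_model.json")
        self.feature_table.to_csv(outdir / "features.csv")
        self.ld_scores.to_csv(outdir / "ld_scores.csv")
        (outdir / "train_dendrogram.nwk").write_text(
            self.dendrogram.to_newick() + "\n"
        )
        import json

        (outdir / "train_report.json").write_text(
            json.dumps(self.report, indent=1, default=str)
        )


@dataclass
class IdentifyResult:
    cluster_table: pd.DataFrame
    dendrogram: Dendrogram
    assignment: ClusterAssignment
    n_individuals: int
    confusion: ConfusionMatrix | None
    report: dict = field(repr=False)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cluster_table.to_csv(outdir / "clusters.csv")
        (outdir / "dendrogram.nwk").write_text(self.dendrogram.to_newick() + "\n")
        if self.confusion is not None:
            self.confusion.counts.to_csv(outdir / "confusion_counts.csv")
        import json

        (outdir / "identify_report.json").write_text(
            json.dumps(self.report, indent=1, default=str)
        )


def prepare_contours(
    contours: Sequence[F0Contour], config: RunConfig
) -> list[F0Contour]:
    """Resample onto the grid and apply the duration filter."""
    resampled = [resample_contour(c, config.resample_step) for c in contours]
    return duration_filter(resampled, config.min_duration)


def _input_digest(contours: Sequence[F0Contour]) -> str:
    h = hashlib.sha256()
    for c in sorted(contours, key=lambda c: c.howl_id):
        h.update(c.howl_id.encode())
        h.update(np.round(c.times, 9).tobytes())
        h.update(np.round(c.freqs, 9).tobytes())
    return h.hexdigest()


def run_train(
    contours: Sequence[F0Contour],
    config: RunConfig | None = None,
    unlabeled_contours: Sequence[F0Contour] | None = None,
) -> TrainResult:
    """Fit the full identification chain on labelled training howls.

    ``unlabeled_contours`` are additional howls of unknown identity (for
    example the survey batch that will later be identified): they take
    part only in fitting the PCA, widening the retained subspace to cover
    variation beyond the training individuals, and are never seen by the
    discriminant stage.  Raises when fewer than two individuals remain
    after the duration filter, or when any individual has fewer than
    three howls; warns when an individual has fewer than five.
    """
    config = config or RunConfig()
    kept = prepare_contours(contours, config)
    if not kept:
        raise HowlIdError("no training contours pass the duration filter")
    labels = [c.individual_label for c in kept]
    if any(lab is None for lab in labels):
        bad = [c.howl_id for c in kept if c.individual_label is None]
        raise HowlIdError(f"unlabelled training howl(s): {bad}")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise HowlIdError(
            f"training needs at least 2 individuals, got {len(counts)}"
        )
    too_few = counts[counts < MIN_HOWLS_PER_INDIVIDUAL]
    if len(too_few):
        raise HowlIdError(
            "individual(s) below the minimum of "
            f"{MIN_HOWLS_PER_INDIVIDUAL} howls: {dict(too_few)}"
        )
    sparse = counts[counts < COMFORTABLE_HOWLS_PER_INDIVIDUAL]
    if len(sparse):
        logger.warning(
            "individual(s) with fewer than %d training howls: %s",
            COMFORTABLE_HOWLS_PER_INDIVIDUAL,
            dict(sparse),
        )

    table = build_feature_table(kept, step=config.resample_step, sd_mode=config.sd_mode)
    pca_table = table
    if unlabeled_contours:
        extra = prepare_contours(unlabeled_contours, config)
        if extra:
            extra_table = build_feature_table(
                extra, step=config.resample_step, sd_mode=config.sd_mode
            )
            pca_table = pd.concat([table, extra_table])
    pca_model = fit_pca(pca_table, scale_mode=config.scale_mode)
    components = select_components(pca_model, config.variance_threshold)
    pc_scores = project(pca_model, table, components)
    lda_model = fit_lda(pc_scores, labels, priors=config.priors)

    predicted = classify(lda_model, pc_scores)
    train_class_acc = float(np.mean(predicted.to_numpy() == np.array(labels, dtype=object)))

    n_lds = min(config.n_lds, lda_model.n_discriminants)
    if n_lds < config.n_lds:
        logger.warning(
            "only %d discriminants available; using them all", n_lds
        )
    ld_scores = project_ld(lda_model, pc_scores, n_lds)
    dendrogram = agnes_cluster(
        ld_scores,
        metric=config.metric,
        linkage=config.linkage,
        height_scale=config.height_scale,
    )
    label_map = dict(zip([c.howl_id for c in kept], labels))
    if config.cut_height is None:
        cut_height = _calibrate_cut(kept, ld_scores, label_map, config)
        logger.info("clustering scale calibrated on training data: %.3g", cut_height)
    else:
        cut_height = float(config.cut_height)
    assignment = cut_dendrogram(dendrogram, cut_height)
    confusion = evaluate_identification(assignment, label_map)

    report = {
        "version": __version__,
        "config": asdict(config),
        "input_digest_sha256": _input_digest(contours),
        "n_howls_input": len(contours),
        "n_howls_after_filter": len(kept),
        "n_howls_pca": int(len(pca_table)),
        "n_individuals": int(len(counts)),
        "howls_per_individual": {str(k): int(v) for k, v in counts.items()},
        "pc_variance_percent": [
            round(float(v) * 100.0, 4) for v in pca_model.variance_fraction
        ],
        "selected_components": [int(i) + 1 for i in components],
        "selected_variance_percent": round(
            float(pca_model.variance_fraction[components].sum() * 100.0), 4
        ),
        "ld_proportion_percent": [
            round(float(v) * 100.0, 4) for v in lda_model.discriminant_proportion
        ],
        "training_classification_accuracy": train_class_acc,
        "training_cluster_accuracy": confusion.accuracy,
        "training_n_clusters": assignment.n_clusters,
        "cut_height": cut_height,
    }
    logger.info(
        "trained on %d howls from %d individuals: DFA accuracy %.1f%%, "
        "cluster accuracy %.1f%% at scale %.3g",
        len(kept),
        len(counts),
        100 * train_class_acc,
        100 * confusion.accuracy,
        cut_height,
    )
    return TrainResult(
        pca_model=pca_model,
        lda_model=lda_model,
        feature_table=table,
        pc_scores=pc_scores,
        ld_scores=ld_scores,
        dendrogram=dendrogram,
        assignment=assignment,
        confusion=confusion,
        cut_height=cut_height,
        report=report,
    )


def _calibrate_cut(
    kept: Sequence[F0Contour],
    ld_scores: pd.DataFrame,
    label_map: dict,
    config: RunConfig,
) -> float:
    """Calibrate the clustering scale on the training LD scores.

    Identification batches in the field are single recording sessions, so
    their within-individual spread lacks the day-to-day component present
    in a multi-session training set.  When session dates are available the
    cut is therefore calibrated on single-session-per-individual subsets
    (one dendrogram per session rank, median cut across them); otherwise
    on the full training dendrogram.
    """
    # rank sessions within each individual so subset r combines every
    # individual's r-th recording session
    session_rank: dict[str, int] = {}
    by_ind: dict[str, list[str]] = {}
    for c in kept:
        ses = by_ind.setdefault(c.individual_label, [])
        key = f"{c.individual_label}|{c.session_date}"
        if key not in session_rank:
            if c.session_date is None:
                session_rank[key] = -1
            else:
                session_rank[key] = sum(
                    1 for s in ses if s is not None
                )
                ses.append(c.session_date)

    ranks = sorted({r for r in session_rank.values() if r >= 0})
    cuts = []
    if ranks:
        for r in ranks:
            ids = [
                c.howl_id
                for c in kept
                if session_rank[f"{c.individual_label}|{c.session_date}"] == r
            ]
            sub = ld_scores.loc[ids]
            sub_labels = {h: label_map[h] for h in ids}
            # need at least two individuals with >= 2 howls in the subset
            counts = pd.Series(list(sub_labels.values())).value_counts()
            if len(counts) < 2 or len(sub) < 4:
                continue
            dend = agnes_cluster(
                sub,
                metric=config.metric,
                linkage=config.linkage,
                height_scale=config.height_scale,
            )
            cuts.append(calibrate_cut_height(dend, sub_labels))
    if cuts:
        return float(np.median(cuts))
    dend = agnes_cluster(
        ld_scores,
        metric=config.metric,
        linkage=config.linkage,
        height_scale=config.height_scale,
    )
    return calibrate_cut_height(dend, label_map)


def run_identify(
    contours: Sequence[F0Contour],
    pca_model: PCAModel,
    lda_model: LDAModel,
    config: RunConfig | None = None,
    cut_height: float | None = None,
) -> IdentifyResult:
    """Project a howl batch through the fitted equations and cluster it.

    ``cut_height`` is the clustering scale, normally the value calibrated
    during training (``TrainResult.cut_height``); it falls back to
    ``config.cut_height``.  Individual labels on the input contours, when
    present for every howl, are used only to score a confusion matrix —
    never for fitting.
    """
    config = config or RunConfig()
    kept = prepare_contours(contours, config)
    if not kept:
        raise HowlIdError("no contours pass the duration filter")
    if len(kept) > MAX_RECOMMENDED_BATCH:
        logger.warning(
            "batch of %d howls exceeds the recommended %d; consider "
            "multiple small batches (50-100 calls) to keep clusters clean",
            len(kept),
            MAX_RECOMMENDED_BATCH,
        )

    table = build_feature_table(kept, step=config.resample_step, sd_mode=config.sd_mode)
    components = np.array(
        [int(c[2:]) - 1 for c in lda_model.pc_columns], dtype=int
    )
    pc_scores = project(pca_model, table, components)
    n_lds = min(config.n_lds, lda_model.n_discriminants)
    ld_scores = project_ld(lda_model, pc_scores, n_lds)

    dendrogram = agnes_cluster(
        ld_scores,
        metric=config.metric,
        linkage=config.linkage,
        height_scale=config.height_scale,
    )
    if cut_height is None:
        cut_height = config.cut_height
    if config.n_clusters is not None:
        assignment = cut_to_k(dendrogram, config.n_clusters)
    elif cut_height is not None:
        assignment = cut_dendrogram(dendrogram, float(cut_height))
    else:
        raise HowlIdError(
            "no clustering scale: pass cut_height (e.g. the training-"
            "calibrated TrainResult.cut_height), set config.cut_height, "
            "or set config.n_clusters"
        )
    n_individuals = count_individuals(assignment)

    labels = {c.howl_id: c.individual_label for c in kept}
    confusion = None
    if all(v is not None for v in labels.values()):
        confusion = evaluate_identification(assignment, labels)

    cluster_table = ld_scores.copy()
    cluster_table["cluster"] = assignment.clusters
    if confusion is not None:
        cluster_table["mapped_individual"] = [
            confusion.cluster_map[k] for k in assignment.clusters
        ]
        cluster_table["known_label"] = [labels[h] for h in cluster_table.index]

    report = {
        "version": __version__,
        "config": asdict(config),
        "input_digest_sha256": _input_digest(contours),
        "n_howls_input": len(contours),
        "n_howls_after_filter": len(kept),
        "n_individuals_estimated": n_individuals,
        "identification_accuracy": (
            None if confusion is None else confusion.accuracy
        ),
    }
    logger.info(
        "identified %d clusters among %d howls%s",
        n_individuals,
        len(kept),
        ""
        if confusion is None
        else f" (accuracy {100 * confusion.accuracy:.1f}%)",
    )
    return IdentifyResult(
        cluster_table=cluster_table,
        dendrogram=dendrogram,
        assignment=assignment,
        n_individuals=n_individuals,
        confusion=confusion,
        report=report,
    )
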