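"""End-to-end orchestration of the self-learning tracing loop.

One round runs: initial trace (or an externally supplied reconstruction) ->
per-segment confidence scoring -> exemplar layers -> balanced sampling ->
wavelet features -> mRMR selection -> SVM training -> classifier-gated
foreground growth -> image adjustment -> re-trace at threshold 1.  The
iterative mode feeds each round's reconstruction back in as the next
round's initial reconstruction, which lets a partially recovered structure
contribute better exemplars (gap regions reached in round *r* become
training material in round *r + 1*).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .classify_grow import adjust_image, grow_foreground, train_classifier
from .confidence import score_segments
from .exemplars import Label, build_label_volume, draw_training_samples
from .features import extract_windows, mwr_feature_matrix, mrmr_select
from .io_formats import Image3D, NeuronTree
from .morphology import MorphologyReport, measure_morphology
from .tracer import TracerConfig, baseline_trace

__all__ = ["PipelineConfig", "RunReport", "run_smarttracing", "run_iterative", "make_feature_fn"]

logger = logging.getLogger(__name__)

# stage keys of the per-round timing log: initial trace, confidence scoring,
# feature selection, classifier training, foreground prediction, final trace
STAGES = ("T_in", "T_s", "T_m", "T_t", "T_p", "T_st")


@dataclass
class PipelineConfig:
    """All knobs of one tracing round; the defaults are the method's
    standard operating point: 16^3 feature windows, 3 wavelet levels, 20
    selected features, default SVM, final trace at background threshold 1.
    """

    confidence_threshold: float = 0.5
    brightfield: bool = False
    layer_radii: tuple[float, float, float] | None = None
    window_side: int = 16
    mwr_levels: int = 3
    wavelet: str = "haar"
    k_features: int = 20
    max_samples_per_class: int = 500
    trace_threshold: int = 1
    connectivity: int = 26
    path_margin: int = 16
    seed: int = 0
    rounds: int = 1
    convergence_ratio: float = 0.05
    tracer: TracerConfig = field(default_factory=TracerConfig)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["tracer"]["soma_seed"] = (
            list(self.tracer.soma_seed)
            if not isinstance(self.tracer.soma_seed, str)
            else self.tracer.soma_seed
        )
        return d


@dataclass
class RunReport:
    initial: MorphologyReport
    final: MorphologyReport
    confident_fraction: float
    n_samples_per_class: int
    n_selected_features: int
    growth_stats: dict
    timings: dict
    seed: int

    @property
    def improvement_ratio(self) -> float:
        """Final total length / initial total length."""
        if self.initial.total_length <= 0:
            return float("inf")
        return self.final.total_length / self.initial.total_length

    def as_dict(self) -> dict:
        return {
            "initial": self.initial.as_dict(),
            "final": self.final.as_dict(),
            "improvement_ratio": self.improvement_ratio,
            "confident_fraction": self.confident_fraction,
            "n_samples_per_class": self.n_samples_per_class,
            "n_selected_features": self.n_selected_features,
            "growth_stats": self.growth_stats,
            "timings": self.timings,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def make_feature_fn(
    img: Image3D,
    side: int,
    levels: int,
    wavelet: str,
    selected: list[int] | None = None,
    chunk: int = 2048,
):
    """Vectorized voxel -> wavelet-feature mapping, chunked to bound memory."""

    def fn(coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=int)
        out = []
        for k in range(0, len(coords), chunk):
            w = extract_windows(img, coords[k : k + chunk], side)
            M = mwr_feature_matrix(w, levels, wavelet)
            out.append(M[:, selected] if selected is not None else M)
        return np.concatenate(out, axis=0)

    return fn


def run_smarttracing(
    img: Image3D,
    initial: NeuronTree | str = "auto",
    cfg: PipelineConfig | None = None,
    debug_dir=None,
) -> tuple[NeuronTree, RunReport]:
    """One full self-learning round; returns the re-traced tree and a report.

    ``initial`` may be a reconstruction from any tracer or ``"auto"`` to run
    the built-in baseline tracer.  Deterministic for a fixed config and
    seed.  Raises :class:`~smarttrace.errors.InsufficientExemplarsError`
    when no confident segment (or no background sample) is available.
    """
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if isinstance(initial, str) and initial == "auto":
        initial_tree = baseline_trace(img, cfg.tracer)
    else:
        initial_tree = initial
    timings["T_in"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = score_segments(
        img,
        initial_tree,
        threshold=cfg.confidence_threshold,
        invert=cfg.brightfield,
        margin=cfg.path_margin,
    )
    timings["T_s"] = time.perf_counter() - t0
    logger.info(
        "confidence: %d/%d segments confident",
        len(report.confident_segments()),
        len(report.records),
    )

    t0 = time.perf_counter()
    lv = build_label_volume(
        img, report, layer_radii=cfg.layer_radii, border_margin=cfg.window_side // 2
    )
    fg_vox, bg_vox = draw_training_samples(
        lv, max_per_class=cfg.max_samples_per_class, seed=cfg.seed
    )
    full_fn = make_feature_fn(img, cfg.window_side, cfg.mwr_levels, cfg.wavelet)
    X = full_fn(np.vstack([fg_vox, bg_vox]))
    y = np.concatenate([np.ones(len(fg_vox), dtype=int), np.zeros(len(bg_vox), dtype=int)])
    selection = mrmr_select(X, y, k=cfg.k_features)
    timings["T_m"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    S = selection.selected_indices
    clf = train_classifier(X[: len(fg_vox), S], X[len(fg_vox) :, S], seed=cfg.seed)
    clf.selected_indices = S
    timings["T_t"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seeds = lv.voxels(Label.FOREGROUND_SAMPLE)
    sel_fn = make_feature_fn(img, cfg.window_side, cfg.mwr_levels, cfg.wavelet, selected=S)
    mask = grow_foreground(img, seeds, clf, sel_fn, connectivity=cfg.connectivity,
                           interior_margin=cfg.window_side // 2)
    timings["T_p"] = time.perf_counter() - t0
    logger.info("growth: %s", mask.stats)

    t0 = time.perf_counter()
    adjusted = adjust_image(img, mask, cfg.trace_threshold)
    root = initial_tree.roots()[0]
    final_cfg = TracerConfig(
        background_threshold=cfg.trace_threshold,
        soma_seed=root.zyx(),
        min_branch_length=cfg.tracer.min_branch_length,
    )
    final_tree = baseline_trace(adjusted, final_cfg)
    timings["T_st"] = time.perf_counter() - t0

    if debug_dir is not None:
        _dump_debug(debug_dir, initial_tree, report, lv, mask, adjusted, final_tree)

    run = RunReport(
        initial=measure_morphology(initial_tree),
        final=measure_morphology(final_tree),
        confident_fraction=report.confident_fraction(),
        n_samples_per_class=len(fg_vox),
        n_selected_features=len(S),
        growth_stats=mask.stats,
        timings=timings,
        seed=cfg.seed,
    )
    for k in STAGES:
        logger.info("stage %s: %.2fs", k, timings.get(k, 0.0))
    return final_tree, run


def run_iterative(
    img: Image3D,
    cfg: PipelineConfig | None = None,
    initial: NeuronTree | str = "auto",
) -> tuple[NeuronTree, list[RunReport]]:
    """Run up to ``cfg.rounds`` rounds, feeding each result into the next.

    Stops early once the total length changes by less than
    ``cfg.convergence_ratio`` (relative) between consecutive rounds.  With
    ``rounds=1`` this is exactly :func:`run_smarttracing`.
    """
    cfg = cfg or PipelineConfig()
    if cfg.rounds < 1:
        raise ValueError("rounds must be >= 1")
    reports: list[RunReport] = []
    current = initial
    tree: NeuronTree | None = None
    prev_len: float | None = None
    for r in range(cfg.rounds):
        tree, rep = run_smarttracing(img, initial=current, cfg=cfg)
        reports.append(rep)
        length = rep.final.total_length
        logger.info("round %d: length %.1f", r + 1, length)
        if prev_len is not None and prev_len > 0:
            if abs(length - prev_len) / prev_len < cfg.convergence_ratio:
                break
        prev_len = length
        current = tree
    return tree, reports


def _dump_debug(debug_dir, initial_tree, report, lv, mask, adjusted, final_tree) -> None:
    import os

    from .io_formats import write_image, write_swc

    os.makedirs(debug_dir, exist_ok=True)
    write_swc(
        initial_tree,
        os.path.join(debug_dir, "initial.swc"),
        color_scores=report.node_scores(),
    )
    write_image(Image3D(lv.labels.astype(np.uint8)), os.path.join(debug_dir, "labels.tif"))
    write_image(
        Image3D(mask.mask.astype(np.uint8) * 255), os.path.join(debug_dir, "mask.tif")
    )
    write_image(adjusted, os.path.join(debug_dir, "adjusted.tif"))
    write_swc(final_tree, os.path.join(debug_dir, "final.swc"))
    with open(os.path.join(debug_dir, "confidence.json"), "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
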