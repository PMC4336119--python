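"""End-to-end segmentation pipeline and evaluation helpers.

Stage order is fixed: homomorphic contrast compression, edge-enhancing
anisotropic diffusion, fractional-differential gradient enhancement, then
recursive normalized-cut partitioning.  Each stage can be skipped
independently; skipping all three enhancement stages reduces the pipeline
to a plain normalized cut of the input.

Configuration is a flat two-level YAML mapping mirroring the module names
(``homomorphic.*``, ``diffusion.*``, ``fractional.*``, ``ncut.*``); shipped
defaults are the parameter set the method was tuned with: dt=0.1, n=50,
(a, b, c, l) = (0.15, 1.4, 0.015, 0.015), Ncut threshold 0.065,
sigma_X = 0.1, sigma_I = 0.3, r = 20.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .diffusion import DiffusionParams, diffuse
from .fractional import build_masks, enhance_with_gradient, fractional_response
from .homomorphic import HomomorphicParams, homomorphic
from .image_io import MIN_SIDE, as_gray, load_gray, save_gray
from .ncut import AffinityParams, SegmentationResult, recursive_ncut
from .phantom import PhantomSpec, dice, make_phantom

__all__ = [
    "HomomorphicConfig",
    "DiffusionConfig",
    "FractionalConfig",
    "NcutConfig",
    "PipelineConfig",
    "PipelineRun",
    "run_pipeline",
    "evaluate",
    "region_dice",
    "write_region_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FractionalConfig:
    order: float = 0.5
    support: int = 5
    variant: str = "gl"
    lam: float = 1.0
    skip: bool = False


@dataclass(frozen=True)
class NcutConfig:
    sigma_i: float = 0.3
    sigma_x: float = 0.1
    radius: float = 20.0
    threshold: float = 0.065
    max_regions: int = 10
    min_region_px: int = 16
    n_candidates: int = 32
    feature: str = "enhanced"  # "enhanced" | "raw"

    def affinity(self) -> AffinityParams:
        return AffinityParams(
            sigma_i=self.sigma_i, sigma_x=self.sigma_x, radius=self.radius
        )


@dataclass(frozen=True)
class HomomorphicConfig(HomomorphicParams):
    skip: bool = False

    def params(self) -> HomomorphicParams:
        d = dataclasses.asdict(self)
        d.pop("skip")
        return HomomorphicParams(**d)


@dataclass(frozen=True)
class DiffusionConfig(DiffusionParams):
    skip: bool = False

    def params(self) -> DiffusionParams:
        d = dataclasses.asdict(self)
        d.pop("skip")
        return DiffusionParams(**d)


@dataclass(frozen=True)
class PipelineConfig:
    homomorphic: HomomorphicConfig = field(default_factory=HomomorphicConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    fractional: FractionalConfig = field(default_factory=FractionalConfig)
    ncut: NcutConfig = field(default_factory=NcutConfig)
    output_dir: str | None = None
    dump_intermediates: bool = False

    # -- YAML round-trip ---------------------------------------------------
    _YAML_KEYS = {
        "fractional": {"lambda": "lam"},  # YAML spelling -> field name
    }

    def to_dict(self) -> dict:
        out: dict = {}
        for block in ("homomorphic", "diffusion", "fractional", "ncut"):
            d = dataclasses.asdict(getattr(self, block))
            rename = {v: k for k, v in self._YAML_KEYS.get(block, {}).items()}
            out[block] = {rename.get(k, k): _plain(v) for k, v in d.items()}
        out["output_dir"] = self.output_dir
        out["dump_intermediates"] = self.dump_intermediates
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        for block, klass in (
            ("homomorphic", HomomorphicConfig),
            ("diffusion", DiffusionConfig),
            ("fractional", FractionalConfig),
            ("ncut", NcutConfig),
        ):
            if block in data:
                sub = dict(data.pop(block))
                for yk, fk in cls._YAML_KEYS.get(block, {}).items():
                    if yk in sub:
                        sub[fk] = sub.pop(yk)
                kwargs[block] = klass(**sub)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


@dataclass
class PipelineRun:
    """Outputs of one pipeline execution."""

    segmentation: SegmentationResult
    intermediates: dict[str, np.ndarray]
    input_image: np.ndarray
    truth: np.ndarray | None = None


def _resolve_input(source, seed: int | None):
    """Accepts an image array, an image path, or a PhantomSpec."""
    if isinstance(source, PhantomSpec):
        if seed is not None:
            source = dataclasses.replace(source, seed=seed)
        img, truth = make_phantom(source)
        return img, truth
    if isinstance(source, (str, Path)):
        img = load_gray(source)
    else:
        img = np.asarray(source)
    return as_gray(img, min_side=MIN_SIDE), None


def run_pipeline(
    source,
    config: PipelineConfig | None = None,
    *,
    seed: int | None = None,
) -> PipelineRun:
    """Run the enabled stages in fixed order and segment the result.

    ``source`` may be a gray image array, a path to an image file, or a
    :class:`~thynseg.phantom.PhantomSpec` (rendered with ``seed`` if
    given).  Intermediate images are kept in the returned
    :class:`PipelineRun` and, when ``config.dump_intermediates`` is set,
    written to ``config.output_dir`` together with the label raster, the
    per-region report and a config snapshot.
    """
    config = config or PipelineConfig()
    img, truth = _resolve_input(source, seed)
    intermediates: dict[str, np.ndarray] = {}

    current = img
    if not config.homomorphic.skip:
        t0 = time.perf_counter()
        current = homomorphic(current, config.homomorphic.params())
        logger.info("homomorphic stage: %.2fs", time.perf_counter() - t0)
    intermediates["enhanced"] = current

    if not config.diffusion.skip:
        t0 = time.perf_counter()
        current = diffuse(current, config.diffusion.params())
        logger.info("diffusion stage: %.2fs", time.perf_counter() - t0)
    intermediates["diffused"] = current

    if not config.fractional.skip:
        t0 = time.perf_counter()
        masks = build_masks(
            config.fractional.order,
            config.fractional.support,
            config.fractional.variant,
        )
        response = fractional_response(current, masks)
        intermediates["gradient"] = response
        current = enhance_with_gradient(
            current, response, masks, lam=config.fractional.lam
        )
        logger.info("fractional stage: %.2fs", time.perf_counter() - t0)
    else:
        intermediates["gradient"] = np.zeros_like(current)

    feature = current if config.ncut.feature == "enhanced" else img
    t0 = time.perf_counter()
    seg = recursive_ncut(
        feature,
        config.ncut.affinity(),
        threshold=config.ncut.threshold,
        max_regions=config.ncut.max_regions,
        min_region_px=config.ncut.min_region_px,
        n_candidates=config.ncut.n_candidates,
    )
    logger.info(
        "ncut stage: %.2fs, %d regions, accepted ncuts %s",
        time.perf_counter() - t0,
        seg.n_regions,
        ["%.5f" % v for v in seg.split_ncuts],
    )

    run = PipelineRun(
        segmentation=seg, intermediates=intermediates, input_image=img, truth=truth
    )
    if config.output_dir is not None:
        _write_artifacts(run, config)
    return run


def _write_artifacts(run: PipelineRun, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg = run.segmentation
    if config.dump_intermediates:
        for name in ("enhanced", "diffused", "gradient"):
            arr = run.intermediates[name]
            save_gray(out / f"{name}.png", np.clip(arr, 0.0, 1.0))
    k = seg.n_regions
    scale = 255 // max(k - 1, 1)
    labels8 = (seg.labels * scale).astype(np.uint8)
    save_gray(out / "labels.png", labels8)
    write_region_report(out / "report.tsv", run.input_image, seg)
    config.to_yaml(out / "config.yaml")


def write_region_report(path, img: np.ndarray, seg: SegmentationResult) -> None:
    """Delimited per-region report: label, pixel count, mean gray."""
    with open(path, "w") as fh:
        fh.write("# accepted_ncuts\t" + ",".join(f"{v:.6f}" for v in seg.split_ncuts) + "\n")
        fh.write("# rejected_ncuts\t" + ",".join(f"{v:.6f}" for v in seg.rejected_ncuts) + "\n")
        fh.write("label\tn_pixels\tmean_gray\n")
        for lab in range(seg.n_regions):
            mask = seg.labels == lab
            fh.write(f"{lab}\t{int(mask.sum())}\t{float(img[mask].mean()):.6f}\n")


def evaluate(labels: np.ndarray, truth: np.ndarray) -> list[dict]:
    """Greedy overlap matching of predicted labels to truth regions.

    Pairs (truth, predicted) are matched greedily by descending pixel
    overlap, each label used at most once; every truth region then gets a
    Dice score against its matched predicted region (0 if unmatched).
    Remaining predicted labels are reported against their best-overlap
    truth region, flagged ``matched=False``.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError(f"shape mismatch: {labels.shape} vs {truth.shape}")
    t_ids = np.unique(truth)
    p_ids = np.unique(labels)
    overlap = np.zeros((t_ids.size, p_ids.size), dtype=np.int64)
    for ti, t in enumerate(t_ids):
        tm = truth == t
        for pi, p in enumerate(p_ids):
            overlap[ti, pi] = int((tm & (labels == p)).sum())

    pairs = sorted(
        ((overlap[ti, pi], ti, pi) for ti in range(t_ids.size) for pi in range(p_ids.size)),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    t_used: dict[int, int] = {}
    p_used: set[int] = set()
    for ov, ti, pi in pairs:
        if ov == 0 or ti in t_used or pi in p_used:
            continue
        t_used[ti] = pi
        p_used.add(pi)

    rows: list[dict] = []
    for ti, t in enumerate(t_ids):
        if ti in t_used:
            pi = t_used[ti]
            d = dice(labels == p_ids[pi], truth == t)
            rows.append(
                {"truth": int(t), "pred": int(p_ids[pi]), "dice": d, "matched": True}
            )
        else:
            rows.append({"truth": int(t), "pred": None, "dice": 0.0, "matched": False})
    for pi, p in enumerate(p_ids):
        if pi in p_used:
            continue
        ti = int(np.argmax(overlap[:, pi]))
        d = dice(labels == p, truth == t_ids[ti])
        rows.append(
            {"truth": int(t_ids[ti]), "pred": int(p), "dice": d, "matched": False}
        )
    return rows


def region_dice(labels: np.ndarray, truth: np.ndarray, truth_id: int) -> float:
    """Dice of one truth region against its greedily matched prediction."""
    for row in evaluate(labels, truth):
        if row["truth"] == truth_id and (row["matched"] or row["pred"] is None):
            return row["dice"]
    return 0.0
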