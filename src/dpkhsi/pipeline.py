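"""End-to-end orchestration: scene -> preprocess -> cluster -> kernels -> CNN -> report.

A single :class:`RunConfig` drives the whole classification pipeline and
every stage's artifact is persisted into a run directory (decision-graph
and threshold-sweep CSVs, the model, the classified map as single-band
ENVI, the evaluation report and a log recording the decided kernel count K,
the cutoff d_c, the selected threshold delta_A and all seeds), so a run
directory alone suffices to regenerate its evaluation.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .hsi_io import HyperCube, read_cube, read_labels, write_cube, write_labels
from .synthetic_data import SceneSpec, make_scene
from .preprocess import extract_patches, extract_subpatches, pca_reduce
from . import density_peaks as dp
from . import kernel_cnn as kc
from .metrics import classification_report

logger = logging.getLogger("dpkhsi")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    # inputs: either paths to an ENVI cube + label map, or a synthetic scene
    cube_path: str | None = None
    labels_path: str | None = None
    scene: SceneSpec = field(default_factory=SceneSpec)
    out_dir: str = "run"
    # preprocessing
    pca_components: int = 8
    patch_size: int = 5
    splits: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # clustering / kernels
    subpatch_size: int = 3
    subpatches_per_patch: int = 1
    cluster_max_samples: int = 400
    kernel_method: str = "mcfsfdp"  # mcfsfdp | cfsfdp_topk | random | kmeans | pca
    n_kernels: int | None = None    # required for cfsfdp_topk/random/kmeans/pca
    dc_fraction: float = dp.DEFAULT_DC_FRACTION
    # network
    pool_p: int = 2
    train: kc.TrainConfig = field(default_factory=kc.TrainConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["scene"] = SceneSpec(**raw.get("scene", {}))
        raw["train"] = kc.TrainConfig(**raw.get("train", {}))
        raw["splits"] = tuple(raw.get("splits", (0.6, 0.2, 0.2)))
        return cls(**raw)


def _kernel_bank(cfg: RunConfig, sub, rng) -> tuple[kc.KernelBank, dict]:
    """Pre-learn the kernel bank by the configured method."""
    info: dict = {"method": cfg.kernel_method}
    blocks = sub.blocks
    if cfg.kernel_method in ("mcfsfdp", "cfsfdp_topk"):
        m = min(len(sub), cfg.cluster_max_samples)
        pick = rng.choice(len(sub), size=m, replace=False)
        pick.sort()
        sampled = type(sub)(blocks[pick], sub.parent_index[pick])
        flat = sampled.blocks.reshape(m, -1)
        dg, D, nneigh = dp.compute_decision_graph(points=flat, dc_fraction=cfg.dc_fraction)
        info["d_c"] = dg.d_c
        if cfg.kernel_method == "mcfsfdp":
            sweep = dp.mcfsfdp_num_kernels(dg)
            k = sweep.num_centers
            info.update(K=k, delta_A=sweep.threshold)
            info["sweep"] = sweep
        else:
            if cfg.n_kernels is None:
                raise ValueError("cfsfdp_topk needs n_kernels")
            k = cfg.n_kernels
            info["K"] = k
        result = dp.select_centers(dg, nneigh, k=k, D=D)
        bank = kc.centers_to_kernels(sampled, result, provenance=cfg.kernel_method)
        info["decision_graph"] = dg
        return bank, info
    if cfg.n_kernels is None:
        raise ValueError(f"{cfg.kernel_method} kernels need n_kernels")
    k = cfg.n_kernels
    n, d = cfg.subpatch_size, blocks.shape[-1]
    info["K"] = k
    if cfg.kernel_method == "random":
        return kc.random_kernels(k, n, d, seed=cfg.seed), info
    flat = blocks.reshape(len(sub), -1)
    if cfg.kernel_method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=4, random_state=cfg.seed).fit(flat)
        kernels = km.cluster_centers_.reshape(k, n, n, d)
    elif cfg.kernel_method == "pca":
        from sklearn.decomposition import PCA

        p = PCA(n_components=k).fit(flat)
        kernels = p.components_.reshape(k, n, n, d)
    else:
        raise ValueError(f"unknown kernel_method {cfg.kernel_method!r}")
    from .kernel_cnn import _normalise_kernels

    return kc.KernelBank(_normalise_kernels(kernels), provenance=cfg.kernel_method), info


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and persist artifacts; returns the run summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.log_level)
    rng = np.random.default_rng(cfg.seed)
    summary: dict = {"seed": cfg.seed, "versions": {
        "python": platform.python_version(), "numpy": np.__version__,
        "dpkhsi": __version__,
    }}
    cfg.to_yaml(out / "config.yaml")

    stage = "load"
    try:
        if cfg.cube_path:
            cube = read_cube(cfg.cube_path)
            labels = read_labels(cfg.labels_path)
            logger.info("loaded cube %sx%sx%s from %s", cube.rows, cube.cols,
                        cube.bands, cfg.cube_path)
        else:
            cube, labels, _ = make_scene(cfg.scene)
            write_cube(cube, out / "scene.hdr", out / "scene.raw")
            write_labels(labels, out / "scene_labels.csv")
            logger.info("synthesised scene %sx%sx%s, %d classes, %.1f dB SNR",
                        cube.rows, cube.cols, cube.bands, cfg.scene.n_classes,
                        cfg.scene.snr_db)

        stage = "preprocess"
        reduced, explained = pca_reduce(cube, cfg.pca_components)
        logger.info("PCA to %d components, explained %.4f", cfg.pca_components, explained)
        summary["pca_explained"] = explained
        train_set, val_set, test_set = extract_patches(
            reduced, labels, s=cfg.patch_size, splits=cfg.splits, seed=cfg.seed
        )
        sub = extract_subpatches(train_set, cfg.subpatch_size,
                                 cfg.subpatches_per_patch, seed=cfg.seed)
        logger.info("patches: train=%d val=%d test=%d; sub-patches=%d",
                    len(train_set), len(val_set), len(test_set), len(sub))

        stage = "cluster"
        bank, info = _kernel_bank(cfg, sub, rng)
        summary["K"] = bank.K
        if "d_c" in info:
            summary["d_c"] = info["d_c"]
            info["decision_graph"].to_csv(out / "decision_graph.csv")
        if "delta_A" in info:
            summary["delta_A"] = info["delta_A"]
            info["sweep"].to_csv(out / "threshold_sweep.csv")
        logger.info("kernel bank: method=%s K=%d", cfg.kernel_method, bank.K)

        stage = "train"
        net = kc.PreLearnedCNN(bank, classes=int(labels.max()), pool_p=cfg.pool_p)
        kc.train_classifier(net, train_set, val_set, cfg.train)
        summary["best_val_acc"] = net.history["best_val_acc"]
        kc.save_model(net, out / "model")
        logger.info("trained FC head: best val acc %.4f", net.history["best_val_acc"])

        stage = "classify"
        pred_map = np.zeros_like(labels)
        for part in (train_set, val_set, test_set):
            if len(part):
                pred, _ = kc.predict(net, part.patches)
                pred_map[part.source_coords[:, 0], part.source_coords[:, 1]] = pred
        write_cube(HyperCube(pred_map[:, :, None].astype(np.int32), interleave="bsq"),
                   out / "classified.hdr", out / "classified.raw")

        stage = "evaluate"
        pred_test, _ = kc.predict(net, test_set.patches)
        report = classification_report(test_set.labels, pred_test,
                                       n_classes=int(labels.max()))
        (out / "eval.json").write_text(json.dumps(report.to_dict(), indent=2))
        summary.update(oa=report.oa, aa=report.aa, kappa=report.kappa)
        logger.info("test OA=%.2f%% AA=%.2f%% kappa=%.4f",
                    report.oa, report.aa, report.kappa)
    except Exception:
        logger.exception("pipeline failed at stage %r; partial artifacts kept in %s",
                         stage, out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
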