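"""End-to-end orchestration: ingestion -> GPA -> warping -> clustering ->
supervised comparison -> associations -> PLS-DA -> biometric model ranking.

`run_pipeline` executes the whole analysis on synthetic or user data and
writes the ranking tables (body-size and shape candidate sets), the
per-K clustering score table, the supervised Delta-ICL/accuracy table,
chi-square association tests, the VIP map, a JSON run manifest and a log.
Outputs are deterministic given the seed: two runs with the same config
produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biometry import collinearity_screen, rank_models
from .clustering import (
    chi_square_association,
    compare_partitions,
    select_k_unsupervised,
)
from .formats import (
    flip_y,
    read_binary_image,
    read_biometric_table,
    read_tps_file,
    write_binary_image,
    write_tps_file,
)
from .morphometrics import (
    ConsensusFrame,
    LandmarkConfiguration,
    build_mask,
    build_pixel_matrix,
    gpa_consensus,
    warp_to_consensus,
)
from .plsda import fit_plsda, vip_map
from .synthetic import SyntheticDesign, generate_biometric_dataset, generate_head_dataset

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

log = logging.getLogger("salamorph")

_CSV_FLOAT = "%.6f"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    With no input paths the synthetic generator supplies the data (the
    default design); otherwise ``tps_path``, ``image_dir`` and
    ``biometry_path`` point at user TPS/PNG/CSV inputs.
    """

    output_dir: str = "salamorph_out"
    seed: int = 0
    # synthetic-or-real ingestion
    tps_path: str | None = None
    image_dir: str | None = None
    biometry_path: str | None = None
    synthetic_grid: tuple[int, int] = (128, 128)
    # consensus frame
    frame_rows: int = 96
    frame_cols: int = 72
    # clustering
    k_min: int = 2
    k_max: int = 6
    starts: int = 10
    # plsda
    plsda_components: int | None = None
    plsda_folds: int = 5
    # misc
    write_warped: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.synthetic_grid = tuple(cfg.synthetic_grid)
        return cfg

    def validate(self) -> None:
        if not (1 < self.k_min <= self.k_max):
            raise ValueError("need 1 < k_min <= k_max")


def _ingest(config: PipelineConfig):
    """Load or synthesize (landmark configs, rasters, labels table, biometry)."""
    if config.tps_path is None:
        design = SyntheticDesign(seed=config.seed)
        log.info("no input paths given: generating synthetic data (seed=%d)", config.seed)
        records, rasters, labels = generate_head_dataset(design, grid=config.synthetic_grid)
        biom = generate_biometric_dataset(design)
    else:
        records = read_tps_file(config.tps_path)
        rasters = [
            read_binary_image(Path(config.image_dir) / (r.image or f"{r.id}.png")) for r in records
        ]
        labels = None
        biom = read_biometric_table(config.biometry_path) if config.biometry_path else None
    configs = [
        LandmarkConfiguration(points=flip_y(r.points, rasters[i].shape[0]), id=r.id)
        for i, r in enumerate(records)
    ]
    if labels is None and biom is not None:
        labels = biom.set_index("id").loc[[c.id for c in configs]].reset_index()
    return records, configs, rasters, labels, biom


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of result tables and arrays.

    Writes (under ``config.output_dir``): scores_k.csv, partitions.csv,
    associations.csv, biometry_ag.csv, biometry_shape.csv, collinearity.csv,
    vip.csv, vip.png, manifest.json, report.txt and pipeline.log.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers if h is not handler):
        stream = logging.StreamHandler(sys.stderr)
        log.addHandler(stream)

    try:
        records, configs, rasters, labels, biom = _ingest(config)
        n = len(configs)
        log.info("ingestion: %d individuals, %d populations", n,
                 labels["population"].nunique() if labels is not None else 0)

        consensus = gpa_consensus(configs)
        log.info("GPA converged in %d iterations; mean Procrustes distance %.4f",
                 consensus.iterations, consensus.procrustes_distances.mean())

        frame = ConsensusFrame.fit(consensus.mean, config.frame_rows, config.frame_cols)
        mask = build_mask(frame)
        log.info("consensus frame %dx%d, head mask J = %d pixels",
                 frame.rows, frame.cols, len(mask))

        warped = [warp_to_consensus(img, c, frame) for img, c in zip(rasters, configs)]
        pm = build_pixel_matrix(warped, mask, frame, ids=[c.id for c in configs])
        log.info("pixel matrix: %d x %d, foreground fraction %.3f", *pm.values.shape,
                 pm.values.mean())
        if config.write_warped:
            wdir = out / "warped"
            wdir.mkdir(exist_ok=True)
            for c, img in zip(configs, warped):
                write_binary_image(img, wdir / f"{c.id}.png")
        # pixel matrix (rows = individuals) + JSON sidecar describing the frame/mask
        pd.DataFrame(pm.values, index=pd.Index(pm.ids, name="id")).to_csv(out / "pixel_matrix.csv")
        with open(out / "pixel_matrix.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "rows": frame.rows, "cols": frame.cols, "scale": frame.scale,
                    "cx": frame.cx, "cy": frame.cy,
                    "mask_index": mask.tolist(),
                },
                fh,
            )

        best_k, scores_k, fits = select_k_unsupervised(
            pm, k_range=range(config.k_min, config.k_max + 1),
            starts=config.starts, seed=config.seed,
        )
        log.info("unsupervised clustering: best K = %d (ICL %.1f)",
                 best_k, scores_k["ICL"].min())
        scores_k.to_csv(out / "scores_k.csv", index=False, float_format=_CSV_FLOAT)
        unsup = fits[best_k].map_labels

        partitions = {"unsupervised partition": unsup}
        assoc_rows = []
        if labels is not None:
            for name, col in (("species", "species"), ("population", "population"),
                              ("habitat", "site_typology")):
                partitions[name] = labels[col].to_numpy()
                chi2, dof, p = chi_square_association(unsup, labels[col])
                assoc_rows.append({"factor": name, "chi2": chi2, "df": dof, "p_value": p})
                log.info("association clusters ~ %s: chi2 = %.2f (df %d), p = %.3g",
                         name, chi2, dof, p)
        part_table = compare_partitions(pm, partitions)
        part_table.to_csv(out / "partitions.csv", index=False, float_format=_CSV_FLOAT)
        pd.DataFrame(assoc_rows).to_csv(out / "associations.csv", index=False,
                                        float_format="%.6g")

        model = fit_plsda(pm, unsup, A=config.plsda_components,
                          folds=config.plsda_folds, seed=config.seed)
        log.info("PLS-DA on the best partition: A = %d, CV accuracy %.3f",
                 model.A, model.cv_accuracy)
        vip = vip_map(model, pm.mask_index, frame)
        pd.DataFrame({
            "row": pm.mask_index[:, 0], "col": pm.mask_index[:, 1], "vip": model.vip,
        }).to_csv(out / "vip.csv", index=False, float_format=_CSV_FLOAT)
        _plot_vip(vip, out / "vip.png")

        results = {
            "best_k": best_k, "scores_k": scores_k, "partitions": part_table,
            "associations": pd.DataFrame(assoc_rows), "plsda": model,
            "pixel_matrix": pm, "consensus": consensus, "frame": frame,
        }

        if biom is not None:
            coll = collinearity_screen(biom)
            coll.to_csv(out / "collinearity.csv", index=False, float_format=_CSV_FLOAT)
            ag_table = rank_models(biom, response="AG")
            shape_table = rank_models(biom, response="shape")
            ag_table.to_csv(out / "biometry_ag.csv", index=False, float_format=_CSV_FLOAT)
            shape_table.to_csv(out / "biometry_shape.csv", index=False, float_format=_CSV_FLOAT)
            log.info("biometry: best AG model %r (w = %.2f); best shape model %r (w = %.2f)",
                     ag_table["model"].iloc[0], ag_table["weight"].iloc[0],
                     shape_table["model"].iloc[0], shape_table["weight"].iloc[0])
            results.update({"biometry_ag": ag_table, "biometry_shape": shape_table,
                            "collinearity": coll})

        manifest = {
            "package": "salamorph",
            "version": __version__,
            "seed": config.seed,
            "n_individuals": n,
            "n_populations": int(labels["population"].nunique()) if labels is not None else None,
            "frame": [config.frame_rows, config.frame_cols],
            "mask_pixels": int(len(mask)),
            "k_range": [config.k_min, config.k_max],
            "starts": config.starts,
            "best_k": int(best_k),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest

        (out / "report.txt").write_text(make_report(out), encoding="utf-8")
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def _plot_vip(vip: np.ndarray, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(vip, cmap="magma")
    fig.colorbar(im, ax=ax, label="VIP")
    ax.set_title("Pixel importance (VIP) for the best partition")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def make_report(output_dir: str | Path) -> str:
    """One-page text summary assembled from the written pipeline outputs."""
    out = Path(output_dir)
    needed = ["manifest.json", "scores_k.csv", "partitions.csv"]
    missing = [f for f in needed if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline outputs in {out}: {missing}")
    manifest = json.loads((out / "manifest.json").read_text())
    scores = pd.read_csv(out / "scores_k.csv")
    parts = pd.read_csv(out / "partitions.csv")

    lines = [
        "salamorph pipeline report",
        "=" * 60,
        f"individuals: {manifest['n_individuals']}   populations: {manifest['n_populations']}",
        f"consensus frame: {manifest['frame'][0]}x{manifest['frame'][1]}"
        f"   head mask: {manifest['mask_pixels']} pixels   seed: {manifest['seed']}",
        "",
        f"Unsupervised clustering (K = {manifest['k_range'][0]}..{manifest['k_range'][1]}): "
        f"best K = {manifest['best_k']}",
        scores.round(1).to_string(index=False),
        "",
        "Supervised comparison (Delta-ICL / accuracy):",
        parts.round(3).to_string(index=False),
    ]
    if (out / "associations.csv").exists():
        assoc = pd.read_csv(out / "associations.csv")
        if len(assoc):
            lines += ["", "Cluster associations (Pearson chi-square):",
                      assoc.round(4).to_string(index=False)]
    for fname, title in (("biometry_ag.csv", "Body size (AG) candidate models:"),
                         ("biometry_shape.csv", "Multivariate shape candidate models:")):
        if (out / fname).exists():
            tab = pd.read_csv(out / fname)
            lines += ["", title,
                      tab[["model", "AICc", "delta", "weight", "p_value"]]
                      .round(3).to_string(index=False)]
    return "\n".join(lines) + "\n"


def save_synthetic_dataset(design: SyntheticDesign, out_dir: str | Path,
                           grid: tuple[int, int] = (128, 128)) -> None:
    """Write a synthetic dataset to disk as TPS + PNG + CSV (the pipeline's
    on-disk input formats)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    records, rasters, labels = generate_head_dataset(design, grid=grid)
    write_tps_file(records, out / "landmarks.tps")
    for rec, raster in zip(records, rasters):
        write_binary_image(raster, out / "images" / rec.image)
    generate_biometric_dataset(design).to_csv(out / "biometry.csv", index=False)
    labels.to_csv(out / "true_labels.csv", index=False)
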