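"""End-to-end pipeline orchestration from a single config.

A run executes a subset of the stages

    simulate -> tissue -> train -> segment -> quantify -> register -> coexist

in dependency order inside a working directory.  Every intermediate artifact
is a plain file (PNG masks, CSV tables, JSON sidecars) so any stage can be
replaced by hand-made fixtures, and a manifest records each output together
with the input hashes, the parameters and the seed, making reruns
bit-reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import cascade as _cascade
from . import coexistence as _coex
from . import quant as _quant
from . import registration as _reg
from . import synthetic as _synth
from . import tissue as _tissue
from . import training as _training
from .features import DEFAULT_SIZES, compute_feature_planes
from .io import read_image, read_mask, write_image, write_mask

__all__ = ["ConfigError", "load_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "tissue", "train", "segment", "quantify", "register", "coexist")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _transforms_from_cfg(entries, n: int) -> list[_reg.SimilarityTransform]:
    if entries is None:
        return [_reg.SimilarityTransform() for _ in range(n)]
    if len(entries) != n:
        raise ConfigError("simulate.transforms must list one transform per section")
    return [
        _reg.SimilarityTransform(
            tx=float(e.get("tx", 0)),
            ty=float(e.get("ty", 0)),
            theta_deg=float(e.get("theta_deg", 0)),
            scale=float(e.get("scale", 1)),
        )
        for e in entries
    ]


def _section_paths(workdir: Path, n: int) -> list[Path]:
    return [workdir / f"section_{i}.png" for i in range(n)]


def run_pipeline(config: dict | str | Path, workdir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    paths_cfg = config.get("paths", {})
    workdir = Path(workdir or paths_cfg.get("workdir", "."))
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", []))
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; valid: {STAGES}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    feature_sizes = tuple(config.get("feature", {}).get("sizes", DEFAULT_SIZES))

    # ---- upfront validation: every stage must find its inputs ----
    will_run = set()
    for s in stages:
        need: list[str] = []
        if s == "tissue":
            if "simulate" not in will_run and not config.get("tissue", {}).get("images"):
                need.append("tissue.images (or a simulate stage)")
        if s == "train":
            if "simulate" not in will_run and not config.get("train", {}).get("annotations"):
                need.append("train.annotations (or a simulate stage)")
        if s == "segment":
            if "train" not in will_run and not config.get("segment", {}).get("model"):
                need.append("segment.model (or a train stage)")
            if "tissue" not in will_run:
                need.append("a tissue stage before segment")
        if s in ("quantify", "register") and "segment" not in will_run and "simulate" not in will_run:
            need.append(f"a segment or simulate stage before {s}")
        if s == "coexist" and "register" not in will_run:
            need.append("a register stage before coexist")
        if need:
            raise ConfigError(f"stage {s!r} is missing prerequisites: {'; '.join(need)}")
        will_run.add(s)

    manifest: dict = {"seed": seed, "stages": {}, "workdir": str(workdir)}

    def record(stage: str, outputs: list[Path], params: dict, inputs: list[Path] = ()) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }

    n_sections = int(config.get("simulate", {}).get("n_sections", 3))
    image_paths: list[Path] = []

    for stage in stages:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                sim = config.get("simulate", {})
                h, w = sim.get("canvas", (300, 300))
                spec = _synth.SyntheticSpec(
                    height=int(h), width=int(w), seed=seed,
                    markers=_synth.MarkerLayout(n_uniform=int(sim.get("n_uniform_dots", 120))),
                )
                tfs = _transforms_from_cfg(sim.get("transforms"), n_sections)
                sections, _ = _synth.generate_serial_set(spec, n_sections, tfs)
                outputs = []
                by_name = {}
                for i, sec in enumerate(sections):
                    img_p = workdir / f"section_{i}.png"
                    write_image(img_p, sec.image)
                    write_mask(workdir / f"tissue_gt_{i}.png", sec.tissue_mask)
                    write_mask(workdir / f"markers_gt_{i}.png", sec.marker_mask)
                    outputs += [img_p, workdir / f"tissue_gt_{i}.png", workdir / f"markers_gt_{i}.png"]
                    by_name[img_p.name] = sec
                ann = _synth.annotations_from_samples(by_name, seed=seed)
                ann_p = workdir / "annotations.csv"
                _training.save_annotations(ann_p, ann)
                outputs.append(ann_p)
                record(stage, outputs, {"n_sections": n_sections, "canvas": [h, w]})
                image_paths = _section_paths(workdir, n_sections)

            elif stage == "tissue":
                tcfg = config.get("tissue", {})
                if tcfg.get("images"):
                    image_paths = [Path(p) for p in tcfg["images"]]
                elif not image_paths:
                    image_paths = _section_paths(workdir, n_sections)
                outputs = []
                meta = {}
                for i, p in enumerate(image_paths):
                    img = read_image(p)
                    region = _tissue.segment_tissue(
                        img,
                        min_area_frac=float(tcfg.get("min_area_frac", 0.0005)),
                        min_compactness=float(tcfg.get("min_compactness", 0.05)),
                    )
                    mp = workdir / f"tissue_{i}.png"
                    write_mask(mp, region.mask)
                    outputs.append(mp)
                    meta[p.name] = {"TA": region.TA, "crop_box": list(region.crop_box)}
                meta_p = workdir / "tissue.json"
                meta_p.write_text(json.dumps(meta, indent=1, sort_keys=True))
                outputs.append(meta_p)
                record(stage, outputs, dict(tcfg), inputs=image_paths)

            elif stage == "train":
                trcfg = config.get("train", {})
                ann_p = Path(trcfg.get("annotations", workdir / "annotations.csv"))
                if not image_paths:
                    image_paths = _section_paths(workdir, n_sections)
                images = {p.name: read_image(p) for p in image_paths}
                shapes = {k: v.shape for k, v in images.items()}
                ann = _training.load_annotations(ann_p, shapes)
                planes = {k: compute_feature_planes(v, feature_sizes) for k, v in images.items()}
                ts = _training.assemble(ann, planes)
                model = _cascade.train_cascade(ts, feature_sizes=feature_sizes, seed=seed)
                model_p = workdir / "model.pkl"
                _cascade.save_model(model_p, model)
                record(stage, [model_p], {"feature_sizes": list(feature_sizes)},
                       inputs=[ann_p, *image_paths])

            elif stage == "segment":
                scfg = config.get("segment", {})
                model_p = Path(scfg.get("model", workdir / "model.pkl"))
                model = _cascade.load_model(model_p)
                if not image_paths:
                    image_paths = _section_paths(workdir, n_sections)
                max_px = scfg.get("max_pixels")
                outputs = []
                for i, p in enumerate(image_paths):
                    img = read_image(p)
                    tmask = read_mask(workdir / f"tissue_{i}.png")
                    if max_px:
                        raw = _cascade.apply_cascade_tiled(model, img, tmask, int(max_px))
                    else:
                        raw = _cascade.apply_cascade(model, img, tmask)
                    seg = _quant.clean_marker_mask(raw)
                    mp = workdir / f"markers_{i}.png"
                    write_mask(mp, seg.M)
                    outputs.append(mp)
                record(stage, outputs, {"max_pixels": max_px}, inputs=[model_p, *image_paths])

            elif stage == "quantify":
                rows = []
                for i in range(n_sections):
                    seg_p = workdir / f"markers_{i}.png"
                    if not seg_p.exists():
                        seg_p = workdir / f"markers_gt_{i}.png"
                    seg = _quant.MarkerSegmentation.from_mask(read_mask(seg_p))
                    tis_p = workdir / f"tissue_{i}.png"
                    if not tis_p.exists():
                        tis_p = workdir / f"tissue_gt_{i}.png"
                    region = _tissue.TissueRegion.from_mask(read_mask(tis_p))
                    dens = _quant.marker_density(seg, region)
                    rows.append({"section": i, "A_M": seg.A_M, "TA": region.TA,
                                 "DM_T_percent": dens.percent})
                dens_p = workdir / "densities.csv"
                pd.DataFrame(rows).to_csv(dens_p, index=False)
                record(stage, [dens_p], {})

            elif stage == "register":
                sections = []
                inputs = []
                for i in range(n_sections):
                    tis_p = workdir / f"tissue_{i}.png"
                    if not tis_p.exists():
                        tis_p = workdir / f"tissue_gt_{i}.png"
                    seg_p = workdir / f"markers_{i}.png"
                    if not seg_p.exists():
                        seg_p = workdir / f"markers_gt_{i}.png"
                    inputs += [tis_p, seg_p]
                    sections.append(
                        (_tissue.TissueRegion.from_mask(read_mask(tis_p)), read_mask(seg_p))
                    )
                regset = _reg.register_set(sections)
                outputs = []
                for i, (tm, mm) in enumerate(zip(regset.tissue_masks, regset.marker_masks)):
                    tp = workdir / f"tissue_reg_{i}.png"
                    mp = workdir / f"markers_reg_{i}.png"
                    write_mask(tp, tm)
                    write_mask(mp, mm)
                    outputs += [tp, mp]
                reg_p = workdir / "registration.json"
                reg_p.write_text(json.dumps({
                    "reference_index": regset.reference_index,
                    "transforms": [t.as_dict() for t in regset.transforms],
                    "GTRO_before": regset.GTRO_before,
                    "GTRO_after": regset.GTRO_after,
                }, indent=1))
                outputs.append(reg_p)
                record(stage, outputs, {}, inputs=inputs)

            elif stage == "coexist":
                ccfg = config.get("coexist", {})
                tissues, markers = [], []
                for i in range(n_sections):
                    tissues.append(read_mask(workdir / f"tissue_reg_{i}.png", frame="registered"))
                    markers.append(read_mask(workdir / f"markers_reg_{i}.png", frame="registered"))
                reg_meta = json.loads((workdir / "registration.json").read_text())
                regset = _reg.RegisteredSet(
                    reference_index=reg_meta["reference_index"],
                    transforms=[_reg.SimilarityTransform(**t) for t in reg_meta["transforms"]],
                    tissue_masks=tissues,
                    marker_masks=markers,
                    GTRO_before=reg_meta["GTRO_before"],
                    GTRO_after=reg_meta["GTRO_after"],
                    shape=tissues[0].shape,
                )
                regions = [
                    _coex.concentration_regions(t, _quant.MarkerSegmentation.from_mask(m))
                    for t, m in zip(tissues, markers)
                ]
                roi = tuple(ccfg["roi"]) if ccfg.get("roi") else None
                report = _coex.coexistence_report(regset, regions, roi=roi)
                pair_p = workdir / "coexistence_pairs.csv"
                marker_p = workdir / "coexistence_markers.csv"
                report.to_dataframe().to_csv(pair_p, index=False)
                report.marker_dataframe().to_csv(marker_p, index=False)
                record(stage, [pair_p, marker_p], {"roi": ccfg.get("roi")})

        except Exception as exc:
            part = workdir / "manifest.partial.json"
            part.write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise RuntimeError(f"stage {stage!r} failed on {workdir}: {exc}") from exc

    manifest_p = workdir / "manifest.json"
    manifest_p.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
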