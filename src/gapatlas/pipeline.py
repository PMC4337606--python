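"""End-to-end pipeline: images/profiles -> boundaries -> atlas -> reports.

A run is driven by a manifest TSV (one row per embryo: ``embryo_id``,
``gene``, ``time_class``, ``group`` and either ``image`` or ``profile``
paths) plus a :class:`~gapatlas.io.PipelineConfig`. Wild-type rows
(``group == 'wt'``) build the atlas; rows grouped ``rnai:<gene>`` are
classified against it. Per-embryo failures are logged and skipped; the
run aborts only when more than 20% of embryos fail.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import rnai
from .atlas import (SpatioTemporalAtlas, aggregate, dataset_census,
                    domains_to_rows)
from .boundaries import fit_profile
from .io import (PipelineConfig, mask_path_for, read_image, read_tsv,
                 write_image, write_tsv)
from .profiles import EmbryoImage, IntensityProfile, extract_profile, \
    normalise_profile
from .synthetic import SyntheticEmbryo, cohort_truth_table

logger = logging.getLogger("gapatlas")

__all__ = ["run_pipeline", "boundaries_from_images", "write_cohort",
           "read_profile_tsv"]

MANIFEST_COLUMNS = {"embryo_id", "gene", "time_class", "group"}


def read_profile_tsv(path) -> list[IntensityProfile]:
    """Read profiles from a tidy TSV (embryo_id, gene, time_class,
    position, value)."""
    df = read_tsv(path)
    out = []
    for (embryo_id, gene, tc), grp in df.groupby(
            ["embryo_id", "gene", "time_class"], sort=True):
        grp = grp.sort_values("position")
        out.append(IntensityProfile(
            positions=grp["position"].to_numpy(),
            values=grp["value"].to_numpy(),
            gene=gene, embryo_id=embryo_id, time_class=tc))
    return out


def _profile_for_row(row: pd.Series, base: Path,
                     config: PipelineConfig) -> IntensityProfile:
    if "image" in row.index and isinstance(row.get("image"), str):
        img_path = base / row["image"]
        mask_p = (base / row["mask"]) if isinstance(row.get("mask"), str) \
            else mask_path_for(img_path)
        image = EmbryoImage(
            pixels=read_image(img_path), mask=read_image(mask_p) > 0,
            gene=row["gene"], embryo_id=row["embryo_id"],
            time_class=row["time_class"],
            anterior_left=bool(row.get("anterior_left", True)),
            inverted_stain=bool(row.get("inverted_stain", False)))
        return extract_profile(
            image, strip_fraction=config.strip_fraction,
            n_bins=config.n_bins, background_pct=config.background_pct,
            scale_pct=config.scale_pct)
    raise ValueError(f"manifest row {row['embryo_id']!r} has no image path")


def boundaries_from_images(manifest: pd.DataFrame, base: Path,
                           config: PipelineConfig) -> tuple[pd.DataFrame, list[str]]:
    """Extract and fit every embryo in a manifest; returns the boundary
    table and the ids of embryos that failed."""
    rows, failed = [], []
    for _, mrow in manifest.iterrows():
        try:
            prof = _profile_for_row(mrow, base, config)
            domains = fit_profile(prof, gene=mrow["gene"],
                                  min_amplitude=config.min_amplitude,
                                  min_width=config.min_width)
            rows.extend(domains_to_rows(mrow["embryo_id"], mrow["gene"],
                                        mrow["time_class"], domains))
        except Exception as err:  # per-embryo isolation
            logger.warning("embryo %s failed: %s", mrow["embryo_id"], err)
            failed.append(str(mrow["embryo_id"]))
    table = pd.DataFrame(rows)
    return table, failed


def run_pipeline(manifest, config: PipelineConfig, outdir,
                 base: Path | None = None) -> dict:
    """Execute extract -> fit -> aggregate (-> perturbation scoring) and
    write all outputs under ``outdir`` with provenance headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        base = base if base is not None else Path(manifest).parent
        manifest = read_tsv(manifest)
    base = base if base is not None else Path(".")
    if manifest.empty:
        raise ValueError("empty manifest")
    missing = MANIFEST_COLUMNS - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")

    table, failed = boundaries_from_images(manifest, base, config)
    if len(failed) > 0.2 * len(manifest["embryo_id"].unique()):
        raise RuntimeError(
            f"{len(failed)} of {manifest['embryo_id'].nunique()} embryos "
            "failed (> 20%)")

    results: dict = {"boundaries": table, "failed": failed}
    write_tsv(table, outdir / "boundaries.tsv", config, config.seed)

    wt_ids = set(manifest.loc[manifest["group"] == "wt", "embryo_id"])
    wt_tab = table[table["embryo_id"].isin(wt_ids)]
    if not wt_tab.empty:
        atlas = aggregate(wt_tab, absent_threshold=config.absent_threshold)
        results["atlas"] = atlas
        write_tsv(atlas.cells, outdir / "atlas.tsv", config, config.seed)
        with open(outdir / "atlas.json", "w") as fh:
            json.dump({"config_hash": config.hash, "seed": config.seed,
                       "atlas": atlas.to_nested_dict()}, fh, indent=1,
                      sort_keys=True)
        census = dataset_census(wt_tab)
        results["census"] = census
        per_gene = pd.DataFrame(
            sorted(census["per_gene"].items()), columns=["gene", "n_embryos"])
        write_tsv(per_gene, outdir / "census.tsv", config, config.seed)

    rnai_groups = sorted(g for g in manifest["group"].unique()
                         if isinstance(g, str) and g.startswith("rnai:"))
    if rnai_groups and "atlas" in results:
        envelope = rnai.build_envelope(results["atlas"], k=config.envelope_k)
        records = []
        for group in rnai_groups:
            kg = group.split(":", 1)[1]
            ids = set(manifest.loc[manifest["group"] == group, "embryo_id"])
            sub = table[table["embryo_id"].isin(ids)]
            if sub.empty:
                logger.warning("no usable embryos in group %s", group)
                continue
            records.extend(rnai.classify_cohort(sub, envelope, kg))
        pen = rnai.penetrance(records)
        edges = rnai.infer_network(
            records, envelope, min_penetrance=config.min_penetrance,
            strong_penetrance=config.strong_penetrance,
            strong_severity=config.strong_severity,
            weak_severity=config.weak_severity)
        results.update(records=records, penetrance=pen, edges=edges,
                       posterior_bias=rnai.posterior_bias(edges))
        write_tsv(pen, outdir / "penetrance.tsv", config, config.seed)
        edge_df = pd.DataFrame([{
            "regulator": e.regulator, "target": e.target, "sign": e.sign,
            "strength": e.strength, "penetrance_pct": e.penetrance_pct,
            "n_affected": e.n_affected, "n_total": e.n_total,
            "median_severity": e.median_severity} for e in edges])
        write_tsv(edge_df, outdir / "network.tsv", config, config.seed)
        (outdir / "network.dot").write_text(rnai.network_to_dot(edges))
    return results


def write_cohort(embryos: list[SyntheticEmbryo], outdir,
                 config: PipelineConfig | None = None,
                 scenario: dict | None = None) -> pd.DataFrame:
    """Write a rendered cohort to disk: TIFF images + masks, ground-truth
    TSV, a manifest TSV, and a YAML scenario description. Returns the
    manifest."""
    import yaml

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for e in embryos:
        row = {"embryo_id": e.embryo_id, "gene": e.gene,
               "time_class": e.time_class,
               "group": f"rnai:{e.perturbed}" if e.perturbed else "wt"}
        if e.image is not None:
            img = Path("images") / f"{e.embryo_id}.tif"
            write_image(e.image, outdir / img)
            write_image(e.mask.astype(float), outdir / mask_path_for(img))
            row["image"] = str(img)
            row["mask"] = str(mask_path_for(img))
        manifest_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    write_tsv(manifest, outdir / "manifest.tsv", config)
    write_tsv(cohort_truth_table(embryos), outdir / "ground_truth.tsv",
              config)
    if scenario is not None:
        with open(outdir / "scenario.yaml", "w") as fh:
            yaml.safe_dump(scenario, fh, sort_keys=True)
    return manifest
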