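"""Batch pipelines binding the stages together.

Two end-to-end paths:

* image pipeline — plate photographs → per-image masks and profiles →
  replicate aggregate → representative selection → plots;
* expression pipeline — DE tables → flag sets, Venn counts and cluster
  summaries.

Every output directory receives a machine-readable provenance record with
the tool version, the resolved configuration and the SHA-256 of each input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import __version__
from .aggregation import AggregateProfile, ReplicateSet, aggregate_profiles, select_representative
from .errors import PatchPigmentError
from .expression import (
    cluster_average_lfc,
    flag_de_2sd,
    flag_de_threshold,
    venn_shared_counts,
)
from .io import (
    read_clusters,
    read_de_table,
    read_image,
    write_baseline,
    write_flags,
    write_mask,
    write_profile,
)
from .masking import MaskingConfig, make_patch_mask
from .profiling import (
    BaselineDistribution,
    baseline_from_images,
    default_baseline,
    extract_profile,
)

log = logging.getLogger("patchpigment")

__all__ = [
    "PipelineConfig",
    "run_image_pipeline",
    "run_baseline_pipeline",
    "run_expression_pipeline",
]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run; serializes to YAML."""

    background_color: str = "33393E"
    background_cutoff: float = 0.15
    noise_fraction: float = 0.02
    hole_fraction: float = 0.20
    connectivity: int = 8
    pigment_color: str = "803D33"
    baseline_file: str | None = None  # None = packaged flat default
    flip: bool = False
    seed: int = 0

    def masking(self) -> MaskingConfig:
        return MaskingConfig(
            background_color=self.background_color,
            background_cutoff=self.background_cutoff,
            noise_fraction=self.noise_fraction,
            hole_fraction=self.hole_fraction,
            connectivity=self.connectivity,
        )

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_provenance(outdir: Path, config: PipelineConfig, inputs: "list[Path]") -> None:
    record = {
        "tool": "patchpigment",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
    }
    (outdir / "provenance.json").write_text(json.dumps(record, indent=2))


def _plot_profiles(outdir: Path, agg: AggregateProfile, rep_index: int, rs: ReplicateSet) -> None:
    x = np.arange(1, 201)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(x, agg.mean - agg.sd, agg.mean + agg.sd, alpha=0.3, label="±1 SD")
    ax.plot(x, agg.mean, label=f"mean of {agg.n} replicates")
    ax.plot(x, rs.profiles[rep_index].mean, lw=0.8, label=f"representative (#{rep_index})")
    ax.axhline(0.5, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("breakpoint (bin 1 = interaction edge)")
    ax.set_ylabel("corrected pigmentation $P_f$")
    ax.set_ylim(-0.02, 1.0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "aggregate_profile.png", dpi=150)
    plt.close(fig)


def run_baseline_pipeline(
    image_paths: "list[str | Path]", config: PipelineConfig, outdir: "str | Path"
) -> BaselineDistribution:
    """Build a baseline distribution from unpigmented wild-type plate images."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in image_paths]
    images = [read_image(p) for p in paths]
    baseline = baseline_from_images(images, config.masking(), config.pigment_color)
    write_baseline(outdir / "baseline.tsv", baseline)
    _write_provenance(outdir, config, paths)
    log.info("baseline from %d images, Pb_min = %.4f", baseline.n_images, baseline.pb_min)
    return baseline


def run_image_pipeline(
    image_paths: "list[str | Path]",
    config: PipelineConfig,
    outdir: "str | Path",
    make_plots: bool = True,
) -> dict:
    """Plate photographs → masks, profiles, aggregate, representative, plots.

    Unreadable or unmaskable files are reported and skipped; the run fails
    only if every input fails.
    """
    from .io import read_baseline  # local import to keep module top light

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in image_paths]
    baseline = (
        read_baseline(config.baseline_file) if config.baseline_file else default_baseline()
    )
    cfg = config.masking()

    profiles, processed, failures = [], [], {}
    for p in paths:
        try:
            img = read_image(p)
            mask = make_patch_mask(img, cfg)
            write_mask(outdir / f"{p.stem}.mask.png", mask)
            prof = extract_profile(
                img, baseline, cfg, config.pigment_color, flip=config.flip
            )
            write_profile(outdir / f"{p.stem}.profile.tsv", prof, {"source": str(p)})
            profiles.append(prof)
            processed.append(p)
        except (OSError, PatchPigmentError, ValueError) as exc:
            log.error("skipping %s: %s", p, exc)
            failures[str(p)] = str(exc)
    if not profiles:
        raise PatchPigmentError(f"all {len(paths)} inputs failed: {failures}")

    rs = ReplicateSet(profiles=profiles, condition_label=outdir.name)
    agg = aggregate_profiles(rs)
    rep = select_representative(rs)
    pd_frame = {
        "bin_index": list(range(1, 201)),
        "mean": agg.mean.tolist(),
        "sd": agg.sd.tolist(),
    }
    import pandas as pd

    pd.DataFrame(pd_frame).to_csv(outdir / "aggregate.tsv", sep="\t", index=False)
    (outdir / "representative.json").write_text(
        json.dumps(
            {"index": rep, "file": str(processed[rep]), "n_replicates": agg.n, "failures": failures},
            indent=2,
        )
    )
    if make_plots:
        _plot_profiles(outdir, agg, rep, rs)
    _write_provenance(outdir, config, paths)
    return {"profiles": profiles, "aggregate": agg, "representative": rep, "failures": failures}


def run_expression_pipeline(
    table_paths: "list[str | Path]",
    config: PipelineConfig,
    outdir: "str | Path",
    rule: str = "2sd",
    min_abs_log2fc: float = 2.0,
    alpha: float = 0.05,
    use_padj: bool = False,
    clusters_path: "str | Path | None" = None,
) -> dict:
    """DE tables → per-table flag sets, Venn counts, cluster summaries."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in table_paths]
    tables = [read_de_table(p) for p in paths]

    flagsets = []
    for t in tables:
        if len(t) == 0:
            log.warning("table %s is empty; zero flags", t.comparison_label)
            continue
        if rule == "2sd":
            flagsets.append(flag_de_2sd(t, alpha=alpha, use_padj=use_padj))
        elif rule == "thresh":
            flagsets.append(
                flag_de_threshold(t, min_abs_log2fc=min_abs_log2fc, alpha=alpha, use_padj=use_padj)
            )
        else:
            raise ValueError(f"unknown rule {rule!r}; use '2sd' or 'thresh'")
    result: dict = {"flagsets": flagsets}
    if flagsets:
        write_flags(outdir / "flags.tsv", flagsets)
    if len(flagsets) >= 2:
        venn = venn_shared_counts(flagsets)
        (outdir / "venn_counts.json").write_text(
            json.dumps(
                {
                    "exactly": venn.exactly,
                    "at_least": venn.at_least,
                    "n_conditions": venn.n_conditions,
                    "union_size": venn.union_size,
                },
                indent=2,
            )
        )
        result["venn"] = venn

    if clusters_path is not None:
        clusters = read_clusters(clusters_path)
        if not clusters:
            log.warning("cluster file %s defines no clusters; summaries skipped", clusters_path)
        else:
            rows = []
            for t in tables:
                for cl in clusters:
                    try:
                        s = cluster_average_lfc(t, cl)
                    except PatchPigmentError as exc:
                        log.warning("%s", exc)
                        continue
                    rows.append(
                        {
                            "comparison": t.comparison_label,
                            "cluster": s.cluster,
                            "mean_log2fc": s.mean_log2fc,
                            "sd_log2fc": s.sd_log2fc,
                            "n_genes_found": s.n_genes_found,
                            "n_missing": len(s.missing_genes),
                        }
                    )
            summary = pd.DataFrame(rows)
            summary.to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
            result["cluster_summary"] = summary
    _write_provenance(outdir, config, paths)
    return result
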