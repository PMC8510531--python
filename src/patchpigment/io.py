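"""Readers and writers for plate images, profiles, baselines and DE tables.

All tabular formats are headered TSV; masks are written as 1-bit PNG with a
JSON corrections log alongside.  Coordinates are 0-based, half-open, image
origin top-left.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .errors import InputError
from .expression import DETable, GeneClusterDef
from .masking import BinaryMask
from .profiling import N_BREAKPOINTS, BaselineDistribution, PigmentationProfile

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "write_profile",
    "read_profile",
    "write_baseline",
    "read_baseline",
    "read_de_table",
    "read_clusters",
    "write_flags",
]


def read_image(path: "str | Path") -> np.ndarray:
    """Read a PNG/TIFF/JPEG plate photograph as an H×W×3 uint8 array."""
    try:
        img = iio.imread(path)
    except Exception as exc:  # imageio plugins raise heterogeneous types
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img[..., :3]


def write_image(path: "str | Path", img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def write_mask(path: "str | Path", mask: BinaryMask) -> None:
    """Write a mask as 1-bit PNG plus ``<path>.log.json`` with the corrections."""
    path = Path(path)
    Image.fromarray(mask.values).convert("1").save(path)
    log = [
        {"operation": r.operation, "components_changed": r.components_changed,
         "pixels_changed": r.pixels_changed}
        for r in mask.corrections_log
    ]
    path.with_suffix(path.suffix + ".log.json").write_text(json.dumps(log, indent=2))


def write_profile(path: "str | Path", profile: PigmentationProfile, metadata: dict | None = None) -> None:
    """Write a profile as TSV (bin_index, mean_Pf, sd_Pf, n_pixels) + JSON metadata."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "bin_index": np.arange(1, N_BREAKPOINTS + 1),
            "mean_Pf": profile.mean,
            "sd_Pf": profile.sd,
            "n_pixels": profile.n_pixels,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {"orientation": profile.orientation}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_profile(path: "str | Path") -> PigmentationProfile:
    df = pd.read_csv(path, sep="\t")
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    orientation = "interaction-first"
    if meta_path.exists():
        orientation = json.loads(meta_path.read_text()).get("orientation", orientation)
    return PigmentationProfile(
        mean=df["mean_Pf"].to_numpy(),
        sd=df["sd_Pf"].to_numpy(),
        n_pixels=df["n_pixels"].to_numpy(),
        orientation=orientation,
    )


def write_baseline(path: "str | Path", baseline: BaselineDistribution) -> None:
    df = pd.DataFrame({"bin_index": np.arange(1, N_BREAKPOINTS + 1), "Pb": baseline.pb})
    df.to_csv(path, sep="\t", index=False)


def read_baseline(path: "str | Path") -> BaselineDistribution:
    df = pd.read_csv(path, sep="\t")
    return BaselineDistribution(pb=df["Pb"].to_numpy())


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_de_table(path: "str | Path", comparison_label: str | None = None) -> DETable:
    """Read a DE results table (TSV or CSV; columns gene_id, log2fc, pvalue[, padj])."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path))
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot parse DE table {path}: {exc}") from exc
    bad = frame.index[frame.get("pvalue", pd.Series(dtype=float)).isna()]
    if len(bad):
        # header is line 1; +2 maps a 0-based row index to its file line number
        raise InputError(f"malformed DE table {path}: missing p-value at line {bad[0] + 2}")
    return DETable(frame=frame, comparison_label=comparison_label or path.stem)


def read_clusters(path: "str | Path") -> list[GeneClusterDef]:
    """Read cluster definitions from a two-column TSV (cluster_name, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if not {"cluster_name", "gene_id"} <= set(df.columns):
        raise InputError(f"cluster file {path} needs columns cluster_name and gene_id")
    out = []
    for name, group in df.groupby("cluster_name", sort=False):
        out.append(GeneClusterDef(name=str(name), gene_ids=tuple(group["gene_id"])))
    return out


def write_flags(path: "str | Path", flagsets: list) -> None:
    """Write one column of flags per comparison over the union of gene ids."""
    universe: set = set()
    for fs in flagsets:
        universe |= set(fs.flags.index)
    df = pd.DataFrame(index=sorted(universe))
    for fs in flagsets:
        df[fs.comparison_label or fs.rule] = fs.flags.reindex(df.index, fill_value=False)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
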