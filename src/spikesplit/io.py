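"""Reading and writing the pipeline's file formats.

Qualitative counts come as a CSV with columns ``trait, class_label, count``
(two rows per trait).  Quantitative trait tables are CSVs with columns
``plant_id, projection, <trait...>``.  Masks are paired 8-bit PNGs named
``<spike_id>_p<projection>_body.png`` / ``..._awns.png`` with 0 = background
and 255 = object; the mm-per-pixel scale is supplied separately.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .morphometry import SpikeMaskPair
from .segregation import SegregationCounts

__all__ = [
    "read_counts_csv",
    "write_counts_csv",
    "read_trait_table",
    "write_trait_table",
    "read_mask_pairs",
    "write_mask_pair",
]


def read_counts_csv(path: str | Path) -> list[SegregationCounts]:
    """Parse qualitative phenotype counts; majority class becomes dominant.

    Raises a ValueError naming the offending row on malformed input.  An
    empty file (header only) yields an empty list.
    """
    df = pd.read_csv(path)
    required = {"trait", "class_label", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: counts CSV needs columns {sorted(required)}, got {list(df.columns)}")
    out: list[SegregationCounts] = []
    for trait, grp in df.groupby("trait", sort=False):
        if len(grp) != 2:
            raise ValueError(
                f"{path}: trait {trait!r} has {len(grp)} class rows, expected 2 "
                f"(rows {list(grp.index + 2)})"
            )
        counts = grp["count"].tolist()
        for row_i, c in zip(grp.index, counts):
            if not float(c).is_integer() or c < 0:
                raise ValueError(f"{path}: row {row_i + 2}: count must be a non-negative integer, got {c!r}")
        out.append(SegregationCounts.from_unordered(str(trait), [int(c) for c in counts]))
    return out


def write_counts_csv(counts: Iterable[SegregationCounts], path: str | Path) -> None:
    rows = []
    for c in counts:
        rows.append({"trait": c.trait, "class_label": "dominant", "count": c.observed[0]})
        rows.append({"trait": c.trait, "class_label": "recessive", "count": c.observed[1]})
    pd.DataFrame(rows, columns=["trait", "class_label", "count"]).to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Trait table CSV -> DataFrame indexed by (plant_id, projection)."""
    df = pd.read_csv(path)
    if not {"plant_id", "projection"}.issubset(df.columns):
        raise ValueError(f"{path}: trait table needs 'plant_id' and 'projection' columns")
    return df.set_index(["plant_id", "projection"])


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index().to_csv(path, index=False, float_format="%.10g")


def _read_mask(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def read_mask_pairs(directory: str | Path, scale: float) -> Iterator[SpikeMaskPair]:
    """Yield mask pairs from ``<spike_id>_p<projection>_{body|awns}.png`` files."""
    directory = Path(directory)
    body_files = sorted(directory.glob("*_p[1-4]_body.png"))
    if not body_files:
        raise FileNotFoundError(f"no '*_p<projection>_body.png' masks found in {directory}")
    for body_path in body_files:
        stem = body_path.name[: -len("_body.png")]
        spike_id, proj_tag = stem.rsplit("_p", 1)
        awn_path = directory / f"{stem}_awns.png"
        if not awn_path.exists():
            raise FileNotFoundError(f"missing awn mask for {body_path.name}: {awn_path.name}")
        yield SpikeMaskPair(
            body=_read_mask(body_path),
            awns=_read_mask(awn_path),
            scale=scale,
            spike_id=spike_id,
            projection=int(proj_tag),
        )


def write_mask_pair(pair: SpikeMaskPair, directory: str | Path) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{pair.spike_id}_p{pair.projection}"
    body_path = directory / f"{stem}_body.png"
    awn_path = directory / f"{stem}_awns.png"
    Image.fromarray(pair.body.astype(np.uint8) * 255).save(body_path)
    Image.fromarray(pair.awns.astype(np.uint8) * 255).save(awn_path)
    return body_path, awn_path
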