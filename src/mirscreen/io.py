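"""On-disk formats: 16-bit TIFF channels, plate maps and score tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import tifffile

from .synthetic_data import FieldImage

PLATEMAP_COLUMNS = ["well", "cell_line", "inhibitor_id", "role", "replicate"]


def field_filenames(well: str, field_index: int) -> tuple[str, str]:
    """`<well>_f<field>_<channel>.tif` naming for the two channels."""
    return (
        f"{well}_f{field_index}_hoechst.tif",
        f"{well}_f{field_index}_caspase.tif",
    )


def write_field(image: FieldImage, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hf, cf = field_filenames(image.well, image.field_index)
    hp, cp = out_dir / hf, out_dir / cf
    tifffile.imwrite(hp, image.hoechst)
    tifffile.imwrite(cp, image.caspase)
    return hp, cp


def read_field(images_dir: str | Path, well: str, field_index: int) -> FieldImage:
    images_dir = Path(images_dir)
    hf, cf = field_filenames(well, field_index)
    return FieldImage(
        hoechst=tifffile.imread(images_dir / hf),
        caspase=tifffile.imread(images_dir / cf),
        well=well,
        field_index=field_index,
    )


def read_platemap(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path)
    missing = [c for c in PLATEMAP_COLUMNS if c not in pm.columns]
    if missing:
        raise ValueError(f"plate map lacks column(s): {missing}")
    return pm


def write_platemap(pm: pd.DataFrame, path: str | Path) -> None:
    pm[PLATEMAP_COLUMNS].to_csv(path, index=False)
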