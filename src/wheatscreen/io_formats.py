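"""Field books, trait registries, thermal matrices and run configuration.

A *field book* is the long-format record of an augmented randomized complete
block trial: one row per experimental unit carrying the genotype id, block
id, a check flag, an optional treatment label and one column per measured
trait.  Checks are replicated once in every block; test genotypes appear
exactly once in the whole trial.  Thermal matrices are 2-D grids of canopy
temperature in degrees Celsius with a JSON sidecar holding the ambient
temperature and payload shape.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignViolationError, FormatError, ParameterError
from .thermal_imaging import ThermalImage

RESERVED_COLUMNS = ("genotype", "block", "is_check", "treatment")


@dataclass(frozen=True)
class TraitInfo:
    units: str = ""
    direction: str = "higher_better"  # or "lower_better"
    description: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise ParameterError(
                f"direction must be higher_better or lower_better, got {self.direction!r}"
            )


@dataclass
class TraitRegistry:
    """Units, preferred direction and description for every trait."""

    entries: dict[str, TraitInfo] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def direction(self, name: str) -> str:
        try:
            return self.entries[name].direction
        except KeyError:
            raise ParameterError(f"trait {name!r} has no registry entry") from None

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.entries]
        if missing:
            raise ParameterError(f"traits missing from registry: {missing}")


def study_trait_registry() -> TraitRegistry:
    """Registry for the traits recorded in the screening study.

    Directions encode agronomic preference: yield components and water
    status up, canopy temperature, water-stress index and injury down.
    """
    up = lambda u, d: TraitInfo(u, "higher_better", d)  # noqa: E731
    down = lambda u, d: TraitInfo(u, "lower_better", d)  # noqa: E731
    return TraitRegistry(
        {
            "GY": up("g", "grain yield per plant"),
            "GPS": up("count", "grains per spike"),
            "GWS": up("g", "grain weight per spike"),
            "HI": up("%", "harvest index"),
            "SF": up("grains per 100 spikelets", "spike fertility"),
            "SL": up("cm", "spike length"),
            "SN": up("count", "spikes per plant"),
            "SPS": up("count", "spikelets per spike"),
            "PHT": up("cm", "plant height"),
            "D50A": down("days", "days to 50% anthesis"),
            "DLR": up("days", "days to leaf rolling"),
            "RWC": up("%", "relative water content"),
            "ELWL": down("%", "excised leaf water loss 0-8 h"),
            "RCI": down("%", "relative cell membrane injury"),
            "FvFm": up("ratio", "maximum quantum yield of photosystem II"),
            "FLSm": down("%/day", "flag leaf senescence rate"),
            "Tc": down("degC", "canopy temperature"),
            "Twet": down("degC", "wet reference temperature"),
            "Tdry": down("degC", "dry reference temperature"),
            "CWSI": down("", "crop water stress index"),
            "Ig": up("", "infrared stomatal-conductance index"),
            "CTD": up("degC", "canopy temperature depression"),
        }
    )


@dataclass
class RunConfig:
    """Tunable analysis parameters with study defaults."""

    selection_intensity_k: float = 2.063
    cv_category_bounds: tuple[float, float] = (10.0, 20.0)
    reference_tail_fraction: float = 0.05
    gdd_base_temp: float = 0.0
    alpha: float = 0.05
    rotation: str = "none"  # or "varimax"
    linkage: str = "ward"  # or "complete" / "average"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cv_category_bounds
        if not lo < hi:
            raise ParameterError("cv_category_bounds must be strictly increasing")
        if not 0.0 < self.reference_tail_fraction < 0.5:
            raise ParameterError("reference_tail_fraction must lie in (0, 0.5)")
        if self.rotation not in ("none", "varimax"):
            raise ParameterError(f"unknown rotation {self.rotation!r}")
        if self.linkage not in ("ward", "complete", "average"):
            raise ParameterError(f"unknown linkage {self.linkage!r}")


@dataclass
class FieldBook:
    """Long-format trial observations.

    ``data`` holds one row per experimental unit with the reserved columns
    ``genotype, block, is_check, treatment`` followed by one numeric column
    per trait.  Missing trait values are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("genotype", "block", "is_check"):
            if col not in self.data.columns:
                raise FormatError(f"field book is missing required column {col!r}")
        if "treatment" not in self.data.columns:
            self.data = self.data.assign(treatment="")
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def blocks(self) -> list[str]:
        return sorted(self.data["block"].astype(str).unique())

    @property
    def checks(self) -> list[str]:
        return sorted(self.data.loc[self.data["is_check"], "genotype"].unique())

    @property
    def tests(self) -> list[str]:
        return sorted(self.data.loc[~self.data["is_check"], "genotype"].unique())

    def validate(self, design: bool = False) -> None:
        """Enforce the augmented-design invariants.

        Always: checks at most once per block, tests at most once overall.
        With ``design=True`` additionally require >= 2 blocks and >= 2
        checks, each check present in every block.
        """
        df = self.data
        chk = df[df["is_check"]]
        dup = chk.groupby(["genotype", "block"], observed=True).size()
        if (dup > 1).any():
            g, b = dup[dup > 1].index[0]
            raise DesignViolationError(
                f"check {g!r} appears {dup.loc[(g, b)]} times in block {b!r}"
            )
        tst = df[~df["is_check"]]
        dup = tst.groupby("genotype", observed=True).size()
        if (dup > 1).any():
            g = dup[dup > 1].index[0]
            raise DesignViolationError(
                f"test genotype {g!r} appears in more than one block"
            )
        if design:
            blocks, checks = self.blocks, self.checks
            if len(blocks) < 2 or len(checks) < 2:
                raise DesignViolationError(
                    f"design analysis needs >=2 blocks and >=2 checks, "
                    f"got {len(blocks)} block(s) and {len(checks)} check(s)"
                )

    def subset_trait(self, trait: str) -> pd.DataFrame:
        """Rows with a finite value for ``trait`` (reserved cols + value)."""
        if trait not in self.trait_names:
            raise ParameterError(f"unknown trait {trait!r}")
        out = self.data[list(RESERVED_COLUMNS) + [trait]].rename(columns={trait: "value"})
        return out[np.isfinite(out["value"].astype(float))].reset_index(drop=True)


# -- field book I/O --------------------------------------------------------

def read_fieldbook(path: str | Path, registry: TraitRegistry | None = None) -> FieldBook:
    """Read a delimited field book (TSV or CSV, sniffed from the header)."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[_first_data_line(path)] else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in ("genotype", "block", "is_check") if c not in df.columns]
    if missing:
        raise FormatError(f"field book {path} is missing column(s) {missing}")
    df["is_check"] = df["is_check"].astype(bool)
    df["genotype"] = df["genotype"].astype(str)
    df["block"] = df["block"].astype(str)
    fb = FieldBook(df)
    if registry is not None:
        registry.require(fb.trait_names)
    return fb


def _first_data_line(path: Path) -> int:
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.startswith("#"):
            return i
    raise FormatError(f"{path} holds no data lines")


def write_fieldbook(fb: FieldBook, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fb.data.to_csv(fh, sep="\t", index=False)


# -- thermal matrix I/O ----------------------------------------------------

def read_thermal_matrix(path: str | Path, metadata_path: str | Path) -> ThermalImage:
    """Read a thermal grid (delimited text or raw float32) plus sidecar.

    The sidecar is JSON with keys ``shape`` ([rows, cols]), ``ambient_temp``
    (degC), ``plant_id`` and ``encoding`` ("text" or "float32").
    """
    path, metadata_path = Path(path), Path(metadata_path)
    try:
        meta = json.loads(metadata_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {metadata_path} is not valid JSON: {exc}") from exc
    for key in ("shape", "ambient_temp", "plant_id"):
        if key not in meta:
            raise FormatError(f"sidecar {metadata_path} is missing key {key!r}")
    shape = tuple(int(v) for v in meta["shape"])
    encoding = meta.get("encoding", "text")
    if encoding == "float32":
        raw = np.fromfile(path, dtype="<f4")
        if raw.size != shape[0] * shape[1]:
            raise FormatError(
                f"{path}: payload holds {raw.size} values, sidecar declares {shape}"
            )
        pixels = raw.reshape(shape).astype(float)
    elif encoding == "text":
        pixels = _read_text_grid(path)
        if pixels.shape != shape:
            raise FormatError(
                f"{path}: payload shape {pixels.shape} differs from sidecar {shape}"
            )
    else:
        raise FormatError(f"unknown thermal encoding {encoding!r}")
    if not np.all(np.isfinite(pixels)):
        r, c = np.argwhere(~np.isfinite(pixels))[0]
        raise FormatError(f"{path}: non-finite temperature at row {r}, column {c}")
    return ThermalImage(
        pixels=pixels,
        ambient_temp=float(meta["ambient_temp"]),
        plant_id=str(meta["plant_id"]),
    )


def _read_text_grid(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    for r, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.replace(";", ",").split(",") if "," in line else line.split()
        parsed = []
        for c, cell in enumerate(cells):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {cell!r}"
                ) from None
        rows.append(parsed)
    if not rows:
        raise FormatError(f"{path} holds no numeric rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged rows (expected width {width})")
    return np.asarray(rows, dtype=float)


def write_thermal_matrix(
    img: ThermalImage,
    path: str | Path,
    metadata_path: str | Path,
    encoding: str = "text",
) -> None:
    path, metadata_path = Path(path), Path(metadata_path)
    if encoding == "float32":
        img.pixels.astype("<f4").tofile(path)
    elif encoding == "text":
        np.savetxt(path, img.pixels, delimiter=",", fmt="%.17g")
    else:
        raise ParameterError(f"unknown thermal encoding {encoding!r}")
    meta = {
        "shape": list(img.pixels.shape),
        "ambient_temp": img.ambient_temp,
        "plant_id": img.plant_id,
        "units": "degC",
        "encoding": encoding,
    }
    metadata_path.write_text(json.dumps(meta, indent=1))
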