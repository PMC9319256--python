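"""Shared readers/writers and structured analysis reports.

Tabular data are CSV with unit-suffixed column names (``titrant_uM``,
``heat_ucal``, ``time_s``, ``response_RU`` ...) so units travel with the
file.  Structures are PDB/mmCIF via gemmi.  Every CLI run emits an
:class:`AnalysisReport` JSON with input digests, parameters, results and
warnings for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import gemmi
import numpy as np
import pandas as pd

from . import __version__
from .bli import Sensorgram
from .hydrodynamics import DosyDecay
from .itc import ITCExperiment
from .titration import TitrationSeries

__all__ = [
    "AnalysisReport",
    "read_table",
    "read_structure",
    "file_digest",
    "read_fasta",
    "write_fasta",
    "write_titration_csv",
    "read_titration_csv",
    "write_itc_csv",
    "read_itc_csv",
    "write_sensorgram_csv",
    "read_sensorgram_csv",
    "write_dosy_csv",
    "read_dosy_csv",
]

logger = logging.getLogger("bindlab")

# full-precision float formatting so CSV round trips are lossless
_FLOAT_FMT = "%.17g"


@dataclass
class AnalysisReport:
    module: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    parameters: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    software_version: str = __version__
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a CSV whose header must match ``schema`` (column -> dtype).

    Non-numeric cells in numeric columns are reported with their row and
    column; extra or missing columns are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    expected = list(schema)
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match schema {expected}"
        )
    if df.empty:
        raise ValueError(f"{path}: no rows")
    out = {}
    for col, dtype in schema.items():
        try:
            out[col] = df[col].astype(dtype)
        except (ValueError, TypeError):
            for i, v in enumerate(df[col]):
                try:
                    dtype(v)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"{path}: non-{dtype.__name__} value {v!r} in column "
                        f"{col!r}, data row {i}"
                    ) from None
            raise
    frame = pd.DataFrame(out)
    logger.info("read %d rows from %s", len(frame), path)
    return frame


_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def read_structure(
    path: str | Path, include_waters: bool = False
) -> dict[str, list[dict]]:
    """Parse PDB/mmCIF into per-chain residue records with backbone coords.

    Returns {chain_name: [{"number", "name", "backbone": {atom: (x,y,z)}}]}.
    Water and other hetero solvent records are excluded by default.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise ValueError(f"cannot read structure {path}: {exc}") from exc
    structure.setup_entities()
    model = structure[0]
    chains: dict[str, list[dict]] = {}
    for chain in model:
        residues = []
        for res in chain:
            if not include_waters and res.is_water():
                continue
            backbone = {}
            for atom in res:
                if atom.name in _BACKBONE_ATOMS:
                    backbone[atom.name] = (atom.pos.x, atom.pos.y, atom.pos.z)
            residues.append(
                {"number": res.seqid.num, "name": res.name, "backbone": backbone}
            )
        if residues:
            chains[chain.name] = residues
    return chains


def backbone_coords(chains: dict[str, list[dict]]) -> np.ndarray:
    """Flatten a read_structure result into an (n, 3) backbone coordinate array."""
    coords = [
        xyz
        for residues in chains.values()
        for res in residues
        for xyz in res["backbone"].values()
    ]
    if not coords:
        raise ValueError("no backbone atoms found")
    return np.asarray(coords, float)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader: {header: sequence}."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            if name is None:
                raise ValueError(f"{path}: sequence data before first header")
            chunks.append(line.upper())
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# dataset round-trip writers/readers

def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"titrant_uM": series.titrant_concs, "signal": series.signal}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_titration_csv(
    path: str | Path, fixed_conc: float, temperature: float = 298.15
) -> TitrationSeries:
    df = read_table(path, {"titrant_uM": float, "signal": float})
    return TitrationSeries(
        fixed_conc=fixed_conc,
        titrant_concs=df["titrant_uM"].to_numpy(),
        signal=df["signal"].to_numpy(),
        temperature=temperature,
    )


def write_itc_csv(exp: ITCExperiment, path: str | Path) -> None:
    pd.DataFrame(
        {"injection_uL": exp.injection_volumes, "heat_ucal": exp.heats}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_itc_csv(
    path: str | Path,
    cell_conc: float,
    syringe_conc: float,
    cell_volume: float,
    temperature: float = 298.15,
) -> ITCExperiment:
    df = read_table(path, {"injection_uL": float, "heat_ucal": float})
    return ITCExperiment(
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        cell_volume=cell_volume,
        injection_volumes=df["injection_uL"].to_numpy(),
        heats=df["heat_ucal"].to_numpy(),
        temperature=temperature,
    )


def write_sensorgram_csv(sg: Sensorgram, path: str | Path) -> None:
    pd.DataFrame({"time_s": sg.time, "response_RU": sg.response}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_sensorgram_csv(
    path: str | Path,
    analyte_conc: float,
    t0_assoc: float = 180.0,
    t0_dissoc: float = 300.0,
) -> Sensorgram:
    df = read_table(path, {"time_s": float, "response_RU": float})
    return Sensorgram(
        time=df["time_s"].to_numpy(),
        response=df["response_RU"].to_numpy(),
        analyte_conc=analyte_conc,
        t0_assoc=t0_assoc,
        t0_dissoc=t0_dissoc,
    )


def write_dosy_csv(decay: DosyDecay, path: str | Path) -> None:
    pd.DataFrame({"x": decay.x, "intensity": decay.intensity}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_dosy_csv(path: str | Path, species_label: str = "") -> DosyDecay:
    df = read_table(path, {"x": float, "intensity": float})
    return DosyDecay(
        x=df["x"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        species_label=species_label,
    )
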