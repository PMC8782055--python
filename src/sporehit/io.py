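"""Readers, writers, configuration and run manifests.

Unit conventions enforced at every I/O boundary: wavenumbers in cm-1
(ascending canonical order), doses in Gy, durations in minutes, space
fluxes in Gy/year.  Spectra are two-column text (wavenumber, intensity;
comma or whitespace separated, ``#`` comments); dose-response tables are
headed CSV; results are written as JSON/CSV twins with a manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import InvalidInputError, ParseError, SchemaError
from .hit_model import DoseResponseDataset
from .ion_physics import IonBeam
from .sers_analysis import MIN_POINTS, Spectrum

__all__ = [
    "load_beam_registry",
    "read_spectrum",
    "write_spectrum",
    "read_dose_response",
    "write_dose_response",
    "write_results",
    "RunConfig",
    "RunManifest",
    "file_digest",
]


def load_beam_registry(path: str | Path | None = None) -> dict[str, IonBeam]:
    """Load ion-beam definitions from YAML/JSON; defaults to the shipped
    He/Ar/Fe registry with the facility exposure parameters."""
    if path is None:
        text = resources.files("sporehit").joinpath("data/beams.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    beams = {}
    for name, entry in raw.items():
        entry = dict(entry)
        entry.setdefault("name", name)
        beams[name] = IonBeam(**entry)
    return beams


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text/CSV spectrum.

    Comma- or whitespace-delimited; ``#`` lines are comments.  Descending
    grids are reversed to ascending; duplicate wavenumbers are rejected.
    """
    path = Path(path)
    nus, ys = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(
                f"{path.name}:{lineno}: expected two columns, got {len(parts)}",
                line_number=lineno,
            )
        try:
            nus.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError:
            raise ParseError(
                f"{path.name}:{lineno}: non-numeric value in {body!r}",
                line_number=lineno,
            ) from None
    if len(nus) < MIN_POINTS:
        raise ParseError(
            f"{path.name}: spectrum too short ({len(nus)} < {MIN_POINTS} points)"
        )
    nu = np.array(nus)
    if len(np.unique(nu)) != len(nu):
        raise ParseError(f"{path.name}: duplicate wavenumbers")
    return Spectrum(nu, np.array(ys), meta={"source": str(path)})


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV with a comment header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("# wavenumber_cm1,intensity\n")
        w = csv.writer(fh)
        for nu, y in zip(spec.wavenumbers, spec.intensities):
            w.writerow([repr(float(nu)), repr(float(y))])


_REQUIRED_DR_COLUMNS = {"ion", "dose_gy", "response_kind"}


def read_dose_response(path: str | Path) -> DoseResponseDataset:
    """Read a dose-response CSV with columns ion, dose_gy, response,
    response_kind and optional counts n, n0.

    When ``response`` is absent, survival responses are derived as n/n0.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED_DR_COLUMNS - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    if "response" not in df.columns and not {"n", "n0"} <= set(df.columns):
        raise SchemaError("need either a 'response' column or both 'n' and 'n0'")
    kinds = set(df["response_kind"].astype(str).unique())
    if len(kinds) != 1:
        raise SchemaError(f"mixed response_kind values: {sorted(kinds)}")
    kind = kinds.pop()
    if kind not in ("survival", "release_ratio"):
        raise SchemaError(f"unknown response_kind {kind!r}")
    ions = set(df["ion"].astype(str).unique())
    if len(ions) != 1:
        raise SchemaError(f"one ion per dataset; found {sorted(ions)}")
    doses = df["dose_gy"].to_numpy(dtype=float)
    if np.any(doses < 0):
        raise SchemaError("negative dose_gy")
    counts = None
    if {"n", "n0"} <= set(df.columns) and df["n"].notna().all():
        counts = list(zip(df["n"].astype(float), df["n0"].astype(float)))
    if "response" in df.columns and df["response"].notna().all():
        responses = df["response"].to_numpy(dtype=float)
    else:
        if counts is None:
            raise SchemaError("response column incomplete and counts unavailable")
        responses = np.array([n / n0 for n, n0 in counts])
    return DoseResponseDataset(
        ion=ions and df["ion"].astype(str).iloc[0],
        doses=doses,
        responses=responses,
        response_kind=kind,
        counts=counts,
        meta={"source": str(path)},
    )


def write_dose_response(data: DoseResponseDataset, path: str | Path) -> None:
    rows = {
        "ion": [data.ion] * len(data),
        "dose_gy": data.doses,
        "response": data.responses,
        "response_kind": [data.response_kind] * len(data),
    }
    if data.counts is not None:
        rows["n"] = [c[0] for c in data.counts]
        rows["n0"] = [c[1] for c in data.counts]
    pd.DataFrame(rows).to_csv(path, index=False)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunConfig:
    """Pipeline configuration; flags given on the CLI override file values."""

    beam_registry: str | None = None
    reference_ion: str = "Fe"
    n_boot: int = 1000
    seed: int = 20220116
    bands: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    output_dir: str = "."

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


@dataclass
class RunManifest:
    """Provenance record written alongside every output batch."""

    tool_version: str = __version__
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    seed: int | None = None
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        payload = {
            "tool_version": self.tool_version,
            "config": self.config,
            "input_digests": self.input_digests,
            "seed": self.seed,
            "timestamp": self.timestamp
            or time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_results(
    records: list[dict],
    path: str | Path,
    manifest: RunManifest | None = None,
) -> None:
    """Write analysis records as JSON and CSV twins (plus a manifest).

    ``path`` is the JSON file; the CSV twin gets the same stem with a .csv
    suffix and the manifest ``<stem>.manifest.json``.
    """
    path = Path(path)
    path.write_text(json.dumps(records, indent=2, sort_keys=True, default=float) + "\n")
    pd.DataFrame.from_records(records).to_csv(path.with_suffix(".csv"), index=False)
    if manifest is not None:
        manifest.write(path.with_name(path.stem + ".manifest.json"))


def read_results(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
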