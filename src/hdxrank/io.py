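"""Spectrum/candidate/feature I/O, run configuration and MS1 pair finding.

Supported spectrum formats are MGF and MSP (via matchms) and plain
two-column whitespace text (``m/z intensity`` per line, ``#``-prefixed
comments; ``# key value`` comment lines are read as metadata, so a
two-column file can carry ``# precursor_mz 256.0042`` etc.).

Candidate lists are CSV (columns Identifier, SMILES and optionally
InChIKey, case-insensitive) or SDF V2000.  MS1 feature tables are CSV with
columns mz, rt, intensity.
"""

from __future__ import annotations

import csv
import logging
import os
import tempfile
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_core import DELTA_HD, neutral_from_mz
from .deuteration import isotope_confusability
from .scoring import Spectrum, Weights

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "FeatureRecord",
    "FeaturePair",
    "read_spectrum",
    "write_spectrum",
    "read_candidates",
    "read_features",
    "find_pairs",
    "atomic_write",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable run parameters with their defaults.

    Tolerances follow the evaluation settings: 5 ppm / 0.001 Da for
    high-resolution data (the alternative documented setting is
    10 ppm / 0.01 Da).  ``epsilon`` is the fragment-pair mass deviation; when
    None it defaults to the combined matching tolerance at the precursor.
    """

    rel_ppm: float = 5.0
    abs_da: float = 0.001
    epsilon: float | None = None
    mode: str = "+"
    max_depth: int = 2
    max_shift: int = 2
    rt_window: float = 0.4          # minutes, MS1 pairing window
    max_x: int = 20
    isolation_window: float = 1.3   # m/z, MS/MS isolation sanity check
    seed: int = 0
    weights: Weights = field(default_factory=Weights)

    def __post_init__(self) -> None:
        if self.rel_ppm <= 0 or self.abs_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.rt_window <= 0:
            raise ValueError("rt_window must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat ``key value``/``key=value`` text config; kwargs override."""
        values: dict = {}
        names = {f.name: f for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.replace("=", " ").partition(" ")
            key, val = key.strip(), val.strip()
            if key == "weights":
                values["weights"] = Weights.from_array(
                    [float(x) for x in val.replace(",", " ").split()])
                continue
            if key not in names:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = names[key].type
            if "int" in str(typ):
                values[key] = int(val)
            elif "float" in str(typ):
                values[key] = float(val)
            else:
                values[key] = val
        cfg = cls(**values)
        return replace(cfg, **overrides) if overrides else cfg


def atomic_write(path: str | Path, text: str) -> None:
    """Write a text file atomically (tmp file + rename); never partial."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _label_from_meta(meta: dict) -> str:
    lab = str(meta.get("label", "normal")).lower()
    return "deuterated" if lab.startswith("deut") or lab in ("hdx", "d") \
        else "normal"


def read_spectrum(path: str | Path, fmt: str | None = None,
                  precursor_mz: float | None = None,
                  mode: str | None = None,
                  label: str | None = None) -> Spectrum:
    """Read one spectrum from a file; format inferred from the extension.

    Explicit ``precursor_mz``/``mode``/``label`` arguments override anything
    found in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        spec = _read_matchms(path, "mgf")
    elif fmt == "msp":
        spec = _read_matchms(path, "msp")
    else:
        spec = _read_two_column(path)
    if precursor_mz is not None:
        spec.precursor_mz = precursor_mz
    if mode is not None:
        spec.mode = mode
    if label is not None:
        spec.label = label
    if spec.mode == "-" and spec.adduct in ("M+H", "M+D"):
        spec.adduct = "M-H" if spec.label == "normal" else "M-D"
    elif spec.label == "deuterated" and spec.adduct == "M+H":
        spec.adduct = "M+D"
    return spec


def _read_matchms(path: Path, fmt: str) -> Spectrum:
    from matchms.importing import load_from_mgf, load_from_msp

    loader = load_from_mgf if fmt == "mgf" else load_from_msp
    specs = list(loader(str(path)))
    if not specs:
        raise ValueError(f"{path}: no spectra found")
    if len(specs) > 1:
        log.warning("%s: %d spectra present, using the first", path,
                    len(specs))
    s = specs[0]
    meta = dict(s.metadata)
    mode = "+"
    charge = meta.get("charge")
    if charge is not None:
        try:
            mode = "-" if int(str(charge).rstrip("+-")
                              if str(charge)[-1] in "+-" else charge) < 0 \
                else "+"
        except (TypeError, ValueError):
            mode = "-" if "-" in str(charge) else "+"
    ionmode = str(meta.get("ionmode", "")).lower()
    if ionmode.startswith("neg"):
        mode = "-"
    prec = meta.get("precursor_mz") or meta.get("pepmass")
    if isinstance(prec, (tuple, list)):
        prec = prec[0]
    return Spectrum(
        mz=np.asarray(s.peaks.mz, dtype=float),
        intensity=np.asarray(s.peaks.intensities, dtype=float),
        precursor_mz=float(prec) if prec else None,
        mode=mode,
        adduct=str(meta.get("adduct", "M+H")).strip("[]+-1 ") or "M+H",
        label=_label_from_meta(meta),
        metadata=meta,
    )


def _read_two_column(path: Path) -> Spectrum:
    mzs: list[float] = []
    intens: list[float] = []
    meta: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            parts = stripped.lstrip("#").split(None, 1)
            if len(parts) == 2:
                meta[parts[0].lower()] = parts[1].strip()
            continue
        cols = stripped.split()
        try:
            mzs.append(float(cols[0]))
            intens.append(float(cols[1]) if len(cols) > 1 else 1.0)
        except (ValueError, IndexError):
            raise ValueError(
                f"{path}:{lineno}: malformed peak line {line!r}") from None
    if not mzs:
        raise ValueError(f"{path}: empty spectrum file")
    prec = meta.get("precursor_mz")
    return Spectrum(
        mz=np.array(mzs), intensity=np.array(intens),
        precursor_mz=float(prec) if prec else None,
        mode=meta.get("mode", "+"),
        adduct=meta.get("adduct", "M+H"),
        label=_label_from_meta(meta),
        metadata=meta,
    )


def write_spectrum(spec: Spectrum, path: str | Path,
                   fmt: str | None = None) -> None:
    """Write a spectrum; round-trips peak count and m/z."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("mgf", "msp"):
        from matchms import Spectrum as MSpectrum
        from matchms.exporting import save_as_mgf, save_as_msp

        meta = {"precursor_mz": spec.precursor_mz or 0.0,
                "ionmode": "positive" if spec.mode == "+" else "negative",
                "label": spec.label}
        m = MSpectrum(mz=spec.mz.astype(float),
                      intensities=spec.intensity.astype(float),
                      metadata=meta, metadata_harmonization=False)
        if path.exists():
            path.unlink()
        (save_as_mgf if fmt == "mgf" else save_as_msp)([m], str(path))
        return
    lines = []
    if spec.precursor_mz is not None:
        lines.append(f"# precursor_mz {spec.precursor_mz:.6f}")
    lines.append(f"# mode {spec.mode}")
    lines.append(f"# adduct {spec.adduct}")
    lines.append(f"# label {spec.label}")
    for mz, inten in zip(spec.mz, spec.intensity):
        lines.append(f"{mz:.6f} {inten:.6f}")
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# candidates and features
# ---------------------------------------------------------------------------

def read_candidates(path: str | Path) -> pd.DataFrame:
    """Candidate list with columns identifier, smiles[, inchikey]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".sdf":
        from rdkit import Chem

        rows = []
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                log.warning("%s: skipping unparsable SDF record %d", path, i)
                continue
            ident = mol.GetProp("_Name") if mol.HasProp("_Name") else str(i)
            rows.append({"identifier": ident or str(i),
                         "smiles": Chem.MolToSmiles(mol)})
        if not rows:
            raise ValueError(f"{path}: no parsable structures")
        return pd.DataFrame(rows)
    df = pd.read_csv(path)
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    if "identifier" not in df.columns or "smiles" not in df.columns:
        raise ValueError(
            f"{path}: need Identifier and SMILES columns, got {list(df.columns)}")
    return df


def read_features(path: str | Path, run_label: str = "normal",
                  ) -> list["FeatureRecord"]:
    df = pd.read_csv(path)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "intensity" not in df.columns:
        df["intensity"] = 1.0
    return [FeatureRecord(float(r.mz), float(r.rt), float(r.intensity),
                          run_label) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# MS1 pair finding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureRecord:
    """One MS1 feature (m/z, retention time in minutes, intensity)."""

    mz: float
    rt: float
    intensity: float = 1.0
    run: str = "normal"

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rt < 0:
            raise ValueError("invalid feature: need mz > 0 and rt >= 0")


@dataclass(frozen=True)
class FeaturePair:
    """A matched normal/deuterated MS1 feature pair with inferred X."""

    normal: FeatureRecord
    deuterated: FeatureRecord
    x: int
    deviation_da: float
    isotope_risk: bool


def find_pairs(normal: Sequence[FeatureRecord],
               deuterated: Sequence[FeatureRecord],
               max_x: int = 20, rt_window: float = 0.4,
               mode: str = "+", rel_ppm: float = 10.0, abs_da: float = 0.01,
               resolution: float | None = None) -> list[FeaturePair]:
    """Untargeted pairing of normal and deuterated MS1 features.

    Neutral masses (normal features as protonated/deprotonated ions, HDX
    features as deuteron adducts/losses) are compared; a pair is kept when
    the difference matches ``k * 1.006277`` for some ``0 <= k <= max_x``
    within tolerance and the retention times agree within ``rt_window``
    minutes.  When ``resolution`` is given, pairs with k >= 1 whose m/z
    needs more than that resolving power to separate a 13C isotopologue
    from a monodeuterated ion are flagged as isotope risks.
    """
    if not normal or not deuterated:
        raise ValueError("both feature tables must be nonempty")
    if rt_window <= 0:
        raise ValueError("rt_window must be positive")
    adduct_h = "M+H" if mode == "+" else "M-H"
    adduct_d = "M+D" if mode == "+" else "M-D"
    pairs: list[FeaturePair] = []
    for fn in normal:
        mass_h = neutral_from_mz(fn.mz, adduct_h)
        for fd in deuterated:
            if abs(fn.rt - fd.rt) > rt_window:
                continue
            mass_d = neutral_from_mz(fd.mz, adduct_d)
            diff = mass_d - mass_h
            tol = max(rel_ppm * fd.mz / 1e6, abs_da)
            k = round(diff / DELTA_HD)
            if k < 0 or k > max_x:
                continue
            dev = abs(diff - k * DELTA_HD)
            if dev > tol:
                continue
            risk = False
            if resolution is not None and k >= 1:
                conf = isotope_confusability(fd.mz)
                risk = resolution < fd.mz / conf.delta_da
            pairs.append(FeaturePair(fn, fd, k, dev, risk))
    return pairs


def flag_isolation_conflicts(pairs: Sequence[FeaturePair],
                             isolation_window: float = 1.3,
                             ) -> list[tuple[FeaturePair, FeaturePair]]:
    """Warn about precursor pairs that co-isolate in MS/MS acquisition.

    When the precursors of two different pairs (in the same run) fall
    within the isolation window of each other, their fragment spectra mix
    and the downstream scores become unreliable; each conflicting pair of
    pairs is logged and returned.
    """
    conflicts = []
    for a_idx in range(len(pairs)):
        for b_idx in range(a_idx + 1, len(pairs)):
            a, b = pairs[a_idx], pairs[b_idx]
            if (a.normal.mz != b.normal.mz
                    and abs(a.normal.mz - b.normal.mz) < isolation_window) \
                    or (a.deuterated.mz != b.deuterated.mz
                        and abs(a.deuterated.mz - b.deuterated.mz)
                        < isolation_window):
                log.warning("precursors of pairs (%.4f, %.4f) and "
                            "(%.4f, %.4f) co-isolate within %.2f m/z",
                            a.normal.mz, a.deuterated.mz, b.normal.mz,
                            b.deuterated.mz, isolation_window)
                conflicts.append((a, b))
    return conflicts


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Results CSV export (all raw and normalised score columns)."""
    atomic_write(path, df.to_csv(index=False))
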