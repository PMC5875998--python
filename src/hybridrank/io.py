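"""Readers and writers for the toolkit's interchange formats.

Spectra travel as MGF; peak lists, features and candidate tables as
CSV/TSV (delimiter sniffed on input, TSV on output to avoid locale comma
issues); configuration and truth tables as YAML. Output writers are
deterministic — stable ordering and fixed float formatting — so reruns are
byte-identical.
"""

from __future__ import annotations

import csv
import os
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .chem import IsotopePattern, get_adduct
from .formula import MassFeature
from .fragment import Ms2Spectrum
from .hsqc import HsqcPeak, HsqcPeakList
from .mixture import TocsyPeak

__all__ = [
    "RunConfig",
    "read_ms2_mgf",
    "write_ms2_mgf",
    "read_peak_table",
    "read_hsqc_csv",
    "read_tocsy_csv",
    "read_candidate_structures",
    "write_ranking",
    "write_scenario",
    "read_scenario",
]


@dataclass
class RunConfig:
    """Validated run-wide settings, serialized alongside every output."""

    tol_ppm: float = 10.0
    ms2_tol_ppm: float = 30.0
    max_dh: float = 0.5
    max_dc: float = 5.0
    w_h: float = 10.0
    w_c: float = 1.0
    tocsy_tol_h: float = 0.02
    adduct_positive: str = "[M+H]+"
    adduct_negative: str = "[M-H]-"
    combination: str = "rank_product"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("tol_ppm", "ms2_tol_ppm", "max_dh", "max_dc", "w_h", "w_c", "tocsy_tol_h"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v <= 0:
                raise ValueError(f"config field {name} must be a positive number, got {v!r}")
        get_adduct(self.adduct_positive)
        get_adduct(self.adduct_negative)
        if self.combination != "rank_product":
            raise ValueError(f"unknown combination method {self.combination!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------- MGF I/O

def read_ms2_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read all spectra from an MGF file.

    Polarity is inferred from the sign of the CHARGE field (default
    positive when absent); the TITLE becomes the spectrum label.
    """
    spectra: list[Ms2Spectrum] = []
    with _mgf.read(os.fspath(path), use_index=False) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            polarity = "positive"
            if charge:
                first = charge[0] if isinstance(charge, (list, tuple)) else charge
                if int(first) < 0:
                    polarity = "negative"
            peaks = tuple(
                (float(m), float(i))
                for m, i in zip(entry["m/z array"], entry["intensity array"])
            )
            ce = float(params.get("collision_energy", 30.0))
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=precursor,
                    polarity=polarity,
                    peaks=peaks,
                    collision_energy=ce,
                    label=str(params.get("title", "")),
                )
            )
    return spectra


def write_ms2_mgf(spectra: Sequence[Ms2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (full float precision, deterministic order)."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            if sp.label:
                fh.write(f"TITLE={sp.label}\n")
            fh.write(f"PEPMASS={sp.precursor_mz!r}\n")
            fh.write(f"CHARGE=1{'+' if sp.polarity == 'positive' else '-'}\n")
            fh.write(f"COLLISION_ENERGY={sp.collision_energy!r}\n")
            for m, i in sp.peaks:
                fh.write(f"{m!r} {i!r}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------- peak tables

_REQUIRED_COLUMNS = {
    "hsqc": ["h_ppm", "c_ppm"],
    "tocsy": ["h1_ppm", "h2_ppm"],
    "ms2": ["mz", "intensity"],
    "feature": ["mz", "polarity", "adduct"],
}


def _read_table(path: str | Path, kind: str) -> pd.DataFrame:
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    # cells come in as strings and go through Python's float() so that
    # full-precision writes round-trip exactly
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    for col in _REQUIRED_COLUMNS[kind]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} for kind {kind!r}")
    numeric = [c for c in _REQUIRED_COLUMNS[kind] if c not in ("polarity", "adduct")]
    for col in numeric:
        converted = []
        for row, raw in enumerate(df[col], start=1):
            if raw is None or (isinstance(raw, float) and pd.isna(raw)):
                raise ValueError(f"{path}: empty cell in column {col!r} at data row {row}")
            try:
                converted.append(float(raw))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} in column {col!r} at data row {row}"
                ) from None
        df[col] = converted
    return df


def read_peak_table(path: str | Path, kind: Literal["hsqc", "tocsy", "ms2", "feature"]):
    """Read a typed peak/feature table from CSV or TSV.

    Returns, by kind: ``hsqc`` → HsqcPeakList (kind from an optional
    ``kind`` column, default experimental), ``tocsy`` → list[TocsyPeak]
    (rows canonicalized h1 ≤ h2), ``ms2`` → list of (mz, intensity),
    ``feature`` → list[MassFeature] (optional ``envelope`` column as
    "mass:abundance;…").
    """
    df = _read_table(path, kind)
    if kind == "hsqc":
        peaks = tuple(
            HsqcPeak(
                float(r.h_ppm),
                float(r.c_ppm),
                float(r.intensity) if "intensity" in df.columns else None,
            )
            for r in df.itertuples()
        )
        list_kind = "experimental"
        if "kind" in df.columns and len(df) and str(df["kind"].iloc[0]) == "predicted":
            list_kind = "predicted"
        label = Path(path).stem
        if "label" in df.columns and len(df):
            label = str(df["label"].iloc[0])
        return HsqcPeakList(label=label, kind=list_kind, peaks=peaks)
    if kind == "tocsy":
        return [TocsyPeak(float(r.h1_ppm), float(r.h2_ppm)) for r in df.itertuples()]
    if kind == "ms2":
        return [(float(r.mz), float(r.intensity)) for r in df.itertuples()]
    # feature
    feats = []
    for r in df.itertuples():
        envelope = None
        if "envelope" in df.columns and isinstance(r.envelope, str) and r.envelope:
            pairs = []
            for tok in r.envelope.split(";"):
                m, a = tok.split(":")
                pairs.append((float(m), float(a)))
            envelope = IsotopePattern.from_pairs(pairs)
        feats.append(
            MassFeature(
                mz=float(r.mz),
                polarity=str(r.polarity),
                adduct=get_adduct(str(r.adduct)),
                isotope_envelope=envelope,
                retention_time=float(r.rt) if "rt" in df.columns else None,
                label=str(r.label) if "label" in df.columns else "",
            )
        )
    return feats


def read_hsqc_csv(path: str | Path, kind: str = "experimental", label: str | None = None) -> HsqcPeakList:
    """Read an HSQC peak table, overriding list kind/label explicitly."""
    lst = read_peak_table(path, "hsqc")
    return HsqcPeakList(
        label=label if label is not None else lst.label, kind=kind, peaks=lst.peaks
    )


def read_tocsy_csv(path: str | Path) -> list[TocsyPeak]:
    return read_peak_table(path, "tocsy")


def read_candidate_structures(path: str | Path) -> dict[str, str]:
    """Read a label + SMILES candidate table (CSV/TSV, or SDF by suffix)."""
    p = Path(path)
    if p.suffix.lower() == ".sdf":
        from rdkit import Chem

        out: dict[str, str] = {}
        for i, mol in enumerate(Chem.SDMolSupplier(os.fspath(p))):
            if mol is None:
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
            out[name] = Chem.MolToSmiles(mol)
        if not out:
            raise ValueError(f"{path}: no parsable structures in SDF")
        return out
    df = pd.read_csv(p, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("label", "smiles"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return {str(r.label): str(r.smiles) for r in df.itertuples()}


# ------------------------------------------------------------- rankings

def write_ranking(results, path: str | Path, style: Literal["nmr_table", "ms2_table", "combined", "formula_table"]) -> None:
    """Write a ranked result table as TSV with fixed float precision.

    Column layouts mirror the summary tables of the workflow: NMR results
    report mean per-dimension shift errors (4 decimals) and the matching
    ratio (2 decimals); MS² results report the max-normalized score
    (4 decimals); combined results report both ranks and the rank product.
    """
    if results is None or (hasattr(results, "__len__") and len(results) == 0):
        raise ValueError("cannot write an empty ranking")
    rows: list[dict] = []
    if style == "nmr_table":
        for rank, res in results:
            rows.append(
                {
                    "label": res.candidate_label,
                    "mean_dh": f"{res.mean_dh:.4f}",
                    "mean_dc": f"{res.mean_dc:.4f}",
                    "matching_ratio": f"{res.matching_ratio:.2f}",
                    "rank": rank,
                }
            )
    elif style == "ms2_table":
        for s in results:
            rows.append(
                {
                    "label": s.candidate_label,
                    "score": f"{s.normalized_score:.4f}",
                    "rank": s.rank,
                }
            )
    elif style == "combined":
        for label, rn, rm, key, rank in results.rows:
            rows.append(
                {
                    "label": label,
                    "nmr_rank": rn,
                    "ms2_rank": rm,
                    "rank_product": f"{key:.1f}",
                    "combined_rank": rank,
                }
            )
    elif style == "formula_table":
        for c in results:
            rows.append(
                {
                    "formula": c.formula.hill(),
                    "ppm_error": f"{c.ppm_error:.4f}",
                    "isotope_score": "" if c.isotope_score is None else f"{c.isotope_score:.4f}",
                    "rdbe": f"{c.rdbe:.1f}",
                    "rank": c.rank,
                }
            )
    else:
        raise ValueError(f"unknown ranking style {style!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- scenarios

def _write_hsqc_csv(path: Path, lst: HsqcPeakList) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["h_ppm", "c_ppm", "label", "kind"])
        for p in lst.peaks:
            w.writerow([repr(p.h_shift), repr(p.c_shift), lst.label, lst.kind])


def write_scenario(scenario, out_dir: str | Path) -> Path:
    """Serialize a synthetic scenario to a directory of plain-text files.

    Layout: ``hsqc_experimental.csv``, ``tocsy.csv``, ``features.csv``,
    ``spectra.mgf``, ``candidates/<feature>/<candidate>.csv``,
    ``structures.csv`` and ``truth.yaml``. Full float precision, so a
    read-back reproduces the in-memory objects exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_hsqc_csv(out / "hsqc_experimental.csv", scenario.experimental_hsqc)
    with open(out / "tocsy.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["h1_ppm", "h2_ppm"])
        for t in scenario.tocsy:
            w.writerow([repr(t.h1), repr(t.h2)])
    with open(out / "features.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "mz", "polarity", "adduct", "envelope"])
        for f in scenario.features:
            mf = f.mass_feature
            env = ""
            if mf.isotope_envelope is not None:
                env = ";".join(
                    f"{m!r}:{a!r}" for m, a in mf.isotope_envelope.isotopologues
                )
            w.writerow([mf.label, repr(mf.mz), mf.polarity, mf.adduct.name, env])
    write_ms2_mgf([f.ms2 for f in scenario.features], out / "spectra.mgf")
    with open(out / "structures.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["feature", "label", "smiles"])
        for f in scenario.features:
            for label, smi in f.candidate_structures.items():
                w.writerow([f.feature_id, label, smi])
    cdir = out / "candidates"
    for f in scenario.features:
        fdir = cdir / f.feature_id
        fdir.mkdir(parents=True, exist_ok=True)
        for i, cand in enumerate(f.candidates):
            _write_hsqc_csv(fdir / f"cand{i:03d}.csv", cand)
    truth = {
        fid: {"candidate": cand, "group": grp}
        for fid, (cand, grp) in scenario.truth.items()
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return out


def read_scenario(scenario_dir: str | Path):
    """Read back the parts of a serialized scenario used by the pipeline.

    Returns a dict with the experimental HSQC list, TOCSY peaks, mass
    features, MS² spectra, candidate peak lists per feature, candidate
    structures per feature, and the truth table.
    """
    d = Path(scenario_dir)
    hsqc = read_peak_table(d / "hsqc_experimental.csv", "hsqc")
    tocsy = read_tocsy_csv(d / "tocsy.csv")
    features = read_peak_table(d / "features.csv", "feature")
    spectra = read_ms2_mgf(d / "spectra.mgf")
    structures: dict[str, dict[str, str]] = {}
    df = pd.read_csv(d / "structures.csv")
    for r in df.itertuples():
        structures.setdefault(str(r.feature), {})[str(r.label)] = str(r.smiles)
    candidates: dict[str, list[HsqcPeakList]] = {}
    for fdir in sorted((d / "candidates").iterdir()):
        lists = []
        for cfile in sorted(fdir.glob("*.csv")):
            lst = read_peak_table(cfile, "hsqc")
            lists.append(lst)
        candidates[fdir.name] = lists
    with open(d / "truth.yaml") as fh:
        truth_raw = yaml.safe_load(fh)
    truth = {fid: (v["candidate"], v["group"]) for fid, v in truth_raw.items()}
    return {
        "experimental_hsqc": hsqc,
        "tocsy": tocsy,
        "features": features,
        "spectra": spectra,
        "candidates": candidates,
        "structures": structures,
        "truth": truth,
    }
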