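"""Readers and writers binding the pipeline stages.

Feature tables travel as CSV (one row per feature, ``ms2_ref`` linking into
an MGF file whose spectrum TITLEs are feature ids); spectra as MGF via
pyteomics; trees as Newick; profiles, manifests and gain reports as JSON;
character maps and identification reports as CSV; matrices as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf

from .errors import InputError, ValidationError
from .identify import IdentificationResult, MSFeature
from .quantify import StrainProfile

FEATURE_COLUMNS = ["feature_id", "rt_min", "uv_nm", "precursor_mz",
                   "adduct", "area", "ms2_ref"]


# --------------------------------------------------------------------------
# Feature tables + spectra
# --------------------------------------------------------------------------

def write_features(features: list[MSFeature], csv_path: str | Path,
                   mgf_path: str | Path | None = None) -> None:
    rows = []
    for f in features:
        rows.append({
            "feature_id": f.feature_id,
            "rt_min": round(f.rt_min, 4),
            "uv_nm": "" if f.uv_lambda_max_nm is None else round(f.uv_lambda_max_nm, 1),
            "precursor_mz": round(f.precursor_mz, 5),
            "adduct": f.assumed_adduct or "",
            "area": round(f.peak_area, 2),
            "ms2_ref": f.feature_id if f.fragments else "",
        })
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(csv_path, index=False)
    if mgf_path is not None:
        spectra = [{
            "m/z array": np.array([mz for mz, _ in f.fragments]),
            "intensity array": np.array([i for _, i in f.fragments]),
            "params": {"title": f.feature_id,
                       "pepmass": (round(f.precursor_mz, 5), None)},
        } for f in features if f.fragments]
        mgf.write(spectra, output=str(mgf_path), file_mode="w")


def read_features(csv_path: str | Path,
                  mgf_path: str | Path | None = None) -> list[MSFeature]:
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise InputError(f"feature table not found: {csv_path}")
    try:
        df = pd.read_csv(csv_path, dtype={"feature_id": str, "ms2_ref": str})
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"no features in {csv_path}") from exc
    missing = set(FEATURE_COLUMNS) - {"uv_nm", "adduct", "ms2_ref"} - set(df.columns)
    if missing:
        raise ValidationError(f"{csv_path}: missing columns {sorted(missing)}")
    if df.empty:
        raise InputError(f"no features in {csv_path}")

    spectra: dict[str, tuple[tuple[float, float], ...]] = {}
    if mgf_path is not None and Path(mgf_path).exists():
        with mgf.MGF(str(mgf_path)) as reader:  # plain reader: empty files are fine
            for spec in reader:
                title = spec["params"]["title"]
                spectra[title] = tuple(zip((float(x) for x in spec["m/z array"]),
                                           (float(x) for x in spec["intensity array"])))
    features = []
    for _, row in df.iterrows():
        ms2_ref = row.get("ms2_ref", "")
        frags = spectra.get(str(ms2_ref), ()) if isinstance(ms2_ref, str) and ms2_ref else ()
        uv = row.get("uv_nm", "")
        features.append(MSFeature(
            feature_id=str(row["feature_id"]),
            rt_min=float(row["rt_min"]),
            precursor_mz=float(row["precursor_mz"]),
            peak_area=float(row["area"]),
            uv_lambda_max_nm=None if pd.isna(uv) or uv == "" else float(uv),
            assumed_adduct=(str(row["adduct"]) if isinstance(row.get("adduct"), str)
                            and row.get("adduct") else None),
            fragments=frags,
        ))
    return features


# --------------------------------------------------------------------------
# Identification reports and profiles
# --------------------------------------------------------------------------

def report_frame(results: list[IdentificationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": r.feature_id,
        "confidence": r.confidence.value,
        "compound": r.compound_label or "",
        "adduct": r.matched_adduct or "",
        "matched_indicators": "+".join(sorted(r.matched_indicators)),
        "n_matched_fragments": r.n_matched_fragments,
        "precursor_error_mda": ("" if r.precursor_error_da is None
                                else round(1000 * r.precursor_error_da, 2)),
        "lox_call": "" if r.lox_call is None else r.lox_call,
        "lox_ranking": ";".join(f"{p}:{n}" for p, n in r.lox_ranking),
        "mk_group": r.mk_group or "",
    } for r in results])


def profile_to_dict(profile: StrainProfile) -> dict:
    return {
        "strain_id": profile.strain_id,
        "species_label": profile.species_label,
        "replicate": profile.replicate,
        "is_area": profile.is_area,
        "missing_internal_standard": profile.missing_internal_standard,
        "compound_areas": profile.compound_areas,
        "normalized": profile.normalized,
        "lox_positions": sorted(profile.lox_positions),
        "marker_groups": sorted(profile.marker_groups),
        "oxo_present": profile.oxo_present,
    }


def profile_from_dict(d: dict) -> StrainProfile:
    return StrainProfile(
        strain_id=d["strain_id"],
        species_label=d.get("species_label"),
        replicate=d.get("replicate"),
        is_area=d.get("is_area"),
        missing_internal_standard=d.get("missing_internal_standard", False),
        compound_areas=dict(d.get("compound_areas") or {}),
        normalized=(dict(d["normalized"]) if d.get("normalized") is not None else None),
        lox_positions=set(d.get("lox_positions") or ()),
        marker_groups=set(d.get("marker_groups") or ()),
        oxo_present=bool(d.get("oxo_present", False)),
    )


def write_profile(profile: StrainProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile_to_dict(profile), indent=2))


def read_profile(path: str | Path) -> StrainProfile:
    p = Path(path)
    if not p.exists():
        raise InputError(f"profile not found: {p}")
    return profile_from_dict(json.loads(p.read_text()))


# --------------------------------------------------------------------------
# Character maps
# --------------------------------------------------------------------------

def read_character_csv(path: str | Path) -> dict[str, int]:
    p = Path(path)
    if not p.exists():
        raise InputError(f"character map not found: {p}")
    df = pd.read_csv(p)
    if not {"tip", "state"} <= set(df.columns):
        raise ValidationError(f"{p}: character CSV needs columns tip,state")
    return {str(row["tip"]): row["state"] for _, row in df.iterrows()}


def write_character_csv(char: dict[str, object], path: str | Path) -> None:
    pd.DataFrame({"tip": list(char), "state": list(char.values())}).to_csv(
        path, index=False)


# --------------------------------------------------------------------------
# Manifests
# --------------------------------------------------------------------------

def write_manifest(path: str | Path, **fields) -> None:
    from . import __version__

    manifest = {"loxotype_version": __version__, **fields}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
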