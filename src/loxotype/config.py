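"""Pipeline configuration: matching tolerances, adducts, rooting, output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Tolerances and conventions shared by the identification pipeline.

    Tolerance defaults are q-ToF-appropriate: 0.02 Da on precursors, 0.05 Da
    on fragments, +/-5 nm on UV lambda_max. Retention time is a soft
    indicator and is only consulted when ``rt_reference`` declares that the
    run's RT axis is on the package's reference scale.
    """

    precursor_tol_da: float = 0.02
    fragment_tol_da: float = 0.05
    uv_tol_nm: float = 5.0
    rt_tol_min: float = 0.5
    mk_rt_window_min: float = 0.5
    adducts: tuple[str, ...] = ("M+Na", "M+H")
    h_transfer: int = 1
    rt_reference: bool = False
    missing_as_na: bool = False
    outgroup: str | None = None
    library_path: str | None = None
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for fld in ("precursor_tol_da", "fragment_tol_da", "uv_tol_nm",
                    "rt_tol_min", "mk_rt_window_min"):
            if getattr(self, fld) <= 0:
                raise ValidationError(f"{fld}={getattr(self, fld)} must be > 0")
        self.adducts = tuple(self.adducts)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adducts"] = list(self.adducts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        """Stable digest of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
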