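"""Physical constants and fixed conventions used throughout the package.

All masses are monoisotopic, in daltons, pinned here (CRC/NIST values) so
that every m/z printed by the package traces back to a single table.
"""

# Monoisotopic atomic masses (Da). The only elements the oxylipin models need.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "O": 15.99491462,
    "Na": 22.98976928,
}

ELECTRON_MASS: float = 0.00054858  # Da

# Singly charged cation adducts: adduct label -> attached cation formula.
ADDUCT_CATION: dict[str, dict[str, int]] = {
    "M+H": {"H": 1},
    "M+Na": {"Na": 1},
}

# UV absorbance classes (lambda_max, nm). The conjugated-diene value is the
# textbook hydroxy-PUFA chromophore; the keto class is the observed 248 nm of
# the m/z 353 markers; the chain-shortened oxo-acid class is this package's
# convention for a conjugated carbonyl polyene.
UV_CONJUGATED_DIENE_NM: float = 235.0
UV_KETO_NM: float = 248.0
UV_OXO_ACID_NM: float = 280.0

# Reference retention times (min) on the package's declared RT scale. The
# marker isomer pairs are the observed values; the rest is a fixed convention
# used by the simulator and, when a run declares `rt_reference`, by the
# matcher as a soft indicator.
REFERENCE_RT_MIN: dict[str, float] = {
    "15-HEPE": 19.5,
    "12-HEPE": 20.1,
    "8-HEPE": 20.7,
    "5-HEPE": 21.4,
    "13,14-HEpETE": 22.3,
    "16,14-HEpETE": 22.6,
    "10,11-HEpETE": 22.9,
    "10,8-HEpETE": 23.4,
    "7,5-HEpETE": 23.9,
    "15-OXO": 16.8,
    "IS": 28.0,
}

# Observed isomer retention-time pairs (min) of the undetermined keto-type
# markers, used for marker-group disambiguation when an RT reference scale
# is declared.
MARKER_RT_PAIRS_MIN: dict[str, tuple[float, float]] = {
    "Mk353#1": (24.2, 21.6),
    "Mk353#2": (21.2, 18.4),
}
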