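"""Seeded synthetic LC-MS/MS feature tables and trees with planted characters.

The generator emulates the statistical structure of the study's data: per
strain, the co-occurring HEPE + epoxy-alcohol pair of every LOX position in
its chemotype, marker-group isomer pairs at m/z 353 with keto-type UV,
occasionally the chain-shortened oxo acid, one spiked internal standard,
ppm-scale Gaussian m/z noise, retention-time jitter, log-normal peak areas,
per-fragment dropout, and a uniform background of decoy features. A fixed
seed fully determines the output (NumPy PCG64 generators keyed by seed and
strain id).
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass

import dendropy
import numpy as np

from . import chem, fragmentation
from .chem import Derivatization
from .constants import (
    MARKER_RT_PAIRS_MIN,
    REFERENCE_RT_MIN,
    UV_CONJUGATED_DIENE_NM,
    UV_KETO_NM,
    UV_OXO_ACID_NM,
)
from .errors import ValidationError
from .identify import MSFeature
from .library import INTERNAL_STANDARD_NAME, default_library
from .phylo import Chemotype

__all__ = ["StrainSpec", "SimulationConfig", "simulate_strain", "simulate_tree",
           "panel_strains"]


@dataclass(frozen=True)
class StrainSpec:
    strain_id: str
    species_label: str
    chemotype: Chemotype
    replicate: int | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model and study-design knobs; the seed fully determines output."""

    strains: tuple[StrainSpec, ...] = ()
    mz_noise_ppm: float = 10.0          # Gaussian sigma on precursor and fragment m/z
    rt_jitter_min: float = 0.15         # Gaussian sigma on retention time
    area_lognormal: tuple[float, float] = (13.0, 0.8)  # (mu, sigma) of ln(area)
    fragment_dropout_prob: float = 0.1
    decoy_feature_rate: float = 2.0     # Poisson mean of background features per strain
    is_area_mean: float = 1.0e6
    seed: int = 0
    adduct: str = "M+Na"
    h_transfer: int = 1

    def __post_init__(self) -> None:
        for fld in ("mz_noise_ppm", "rt_jitter_min", "decoy_feature_rate"):
            if getattr(self, fld) < 0:
                raise ValidationError(f"{fld} must be >= 0")
        if not 0.0 <= self.fragment_dropout_prob <= 1.0:
            raise ValidationError("fragment_dropout_prob must lie in [0, 1]")

    @classmethod
    def noiseless(cls, strains: tuple[StrainSpec, ...] = (), seed: int = 0,
                  **kwargs) -> "SimulationConfig":
        """Exact theoretical features: no noise, no dropout, no decoys."""
        return cls(strains=strains, mz_noise_ppm=0.0, rt_jitter_min=0.0,
                   area_lognormal=(13.0, 0.0), fragment_dropout_prob=0.0,
                   decoy_feature_rate=0.0, seed=seed, **kwargs)


def _strain_rng(cfg: SimulationConfig, strain_id: str) -> np.random.Generator:
    digest = hashlib.sha256(strain_id.encode()).digest()
    return np.random.default_rng([cfg.seed, int.from_bytes(digest[:4], "big")])


def _ppm(rng: np.random.Generator, mz: float, sigma_ppm: float) -> float:
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6) if sigma_ppm else mz


def _area(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    mu, sigma = cfg.area_lognormal
    return float(np.exp(mu + (rng.normal(0.0, sigma) if sigma else 0.0)))


def _fragments(rng: np.random.Generator, cfg: SimulationConfig,
               ions) -> tuple[tuple[float, float], ...]:
    kept = [ion for ion in ions
            if cfg.fragment_dropout_prob == 0.0
            or rng.random() >= cfg.fragment_dropout_prob]
    if not kept:
        return ()
    # Relative intensities are cosmetic (matching is presence-based).
    intens = rng.dirichlet(np.ones(len(kept))) * 100.0 if len(kept) > 1 else np.array([100.0])
    return tuple((_ppm(rng, ion.mz, cfg.mz_noise_ppm), float(i))
                 for ion, i in zip(kept, intens))


def simulate_strain(cfg: SimulationConfig, strain: StrainSpec) -> list[MSFeature]:
    """Synthetic feature list for one strain; deterministic under the config seed."""
    for p in strain.chemotype.lox_positions:
        if p not in fragmentation.SUPPORTED_LOX_POSITIONS:
            raise ValidationError(f"chemotype LOX position {p} unsupported")
    rng = _strain_rng(cfg, strain.strain_id)
    deriv = Derivatization.METHYL_ESTER
    features: list[MSFeature] = []

    def rt_of(name: str) -> float:
        base = REFERENCE_RT_MIN.get(name, 20.0)
        return max(0.0, base + (rng.normal(0.0, cfg.rt_jitter_min)
                                if cfg.rt_jitter_min else 0.0))

    def add(name: str, species, uv: float | None, ions=(), rt: float | None = None,
            area: float | None = None) -> None:
        mz_exact, _ = chem.adduct_mz(species, deriv, cfg.adduct)
        features.append(MSFeature(
            feature_id=f"{strain.strain_id}:{name}" + (f"@{rt:.1f}" if rt is not None else ""),
            rt_min=rt if rt is not None else rt_of(name),
            precursor_mz=_ppm(rng, mz_exact, cfg.mz_noise_ppm),
            peak_area=area if area is not None else _area(rng, cfg),
            uv_lambda_max_nm=uv,
            assumed_adduct=cfg.adduct,
            fragments=_fragments(rng, cfg, ions),
        ))

    for p in sorted(strain.chemotype.lox_positions):
        pathway = fragmentation.pathway_products(p)
        if p != 14:  # the 14-LOX pathway is evidenced by its epoxy-alcohol only
            add(pathway.hepe.name, pathway.hepe, UV_CONJUGATED_DIENE_NM,
                fragmentation.alpha_cleavage_ions(pathway.hepe, deriv, cfg.adduct,
                                                  cfg.h_transfer))
        epoxy = pathway.primary_epoxy_alcohol
        add(epoxy.name, epoxy, None,
            fragmentation.diagnostic_ions(epoxy, deriv, cfg.adduct, cfg.h_transfer))

    keto = chem.keto_epa()
    for group in sorted(strain.chemotype.marker_groups):
        if group not in MARKER_RT_PAIRS_MIN:
            raise ValidationError(f"unknown marker group {group!r}")
        for i, rt in enumerate(MARKER_RT_PAIRS_MIN[group], start=1):
            jitter = rng.normal(0.0, cfg.rt_jitter_min) if cfg.rt_jitter_min else 0.0
            add(f"{group}-iso{i}", keto, UV_KETO_NM, rt=max(0.0, rt + jitter))

    if strain.chemotype.oxo_present:
        add("15-OXO", chem.oxo15(), UV_OXO_ACID_NM)

    # internal standard, always present
    lib_is = [e for e in default_library(deriv, (cfg.adduct,))
              if e.name == INTERNAL_STANDARD_NAME][0]
    features.append(MSFeature(
        feature_id=f"{strain.strain_id}:IS",
        rt_min=rt_of(INTERNAL_STANDARD_NAME),
        precursor_mz=_ppm(rng, lib_is.expected_adduct_mzs[cfg.adduct], cfg.mz_noise_ppm),
        peak_area=float(cfg.is_area_mean * np.exp(
            rng.normal(0.0, cfg.area_lognormal[1]) if cfg.area_lognormal[1] else 0.0)),
        assumed_adduct=cfg.adduct,
    ))

    n_decoys = int(rng.poisson(cfg.decoy_feature_rate)) if cfg.decoy_feature_rate else 0
    for i in range(n_decoys):
        features.append(MSFeature(
            feature_id=f"{strain.strain_id}:decoy{i + 1}",
            rt_min=float(rng.uniform(5.0, 30.0)),
            precursor_mz=float(rng.uniform(150.0, 400.0)),
            peak_area=_area(rng, cfg),
        ))
    return features


def panel_strains(n_per_species: int = 1) -> tuple[StrainSpec, ...]:
    """StrainSpecs replicating the study's species panel."""
    from .panel import PANEL_CHEMOTYPES

    specs = []
    for species, chemotype in PANEL_CHEMOTYPES.items():
        for i in range(1, n_per_species + 1):
            specs.append(StrainSpec(
                strain_id=f"{species}-S{i}", species_label=species,
                chemotype=chemotype))
    return tuple(specs)


# --------------------------------------------------------------------------
# Random trees with planted binary characters
# --------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, n_gains: int = 1
                  ) -> tuple[dendropy.Tree, dict[str, int], int]:
    """Random rooted binary tree plus a character gained ``n_gains`` times.

    The gain clades are chosen disjoint and such that no internal node ends
    up with all children present, so the planted count equals the
    irreversible-gain parsimony minimum by construction. Raises when the
    topology cannot host that many independent gains.
    """
    if n_tips < 2:
        raise ValidationError(f"n_tips={n_tips} must be >= 2")
    pyrng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node(taxon=taxon)
        nodes.append(leaf)
    while len(nodes) > 1:
        a = nodes.pop(pyrng.randrange(len(nodes)))
        b = nodes.pop(pyrng.randrange(len(nodes)))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    tree.seed_node = nodes[0]

    if n_gains == 0:
        return tree, {t.label: 0 for t in taxa}, 0

    candidates = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    pyrng.shuffle(candidates)
    chosen: list = []

    def tips_below(node) -> set[str]:
        return {l.taxon.label for l in node.leaf_iter()}

    def ok(cand) -> bool:
        trial = chosen + [cand]
        covered: set[str] = set()
        for u in trial:
            covered |= tips_below(u)
        for u in trial:
            for v in trial:
                if u is not v and tips_below(u) & tips_below(v):
                    return False
            # the parent of each gain must keep one fully uncovered child
            siblings = u.parent_node.child_nodes()
            if not any(not (tips_below(s) & covered) for s in siblings if s is not u):
                return False
        return True

    for cand in candidates:
        if len(chosen) == n_gains:
            break
        if ok(cand):
            chosen.append(cand)
    if len(chosen) < n_gains:
        raise ValidationError(
            f"cannot plant {n_gains} independent gains on a {n_tips}-tip topology")
    present: set[str] = set()
    for node in chosen:
        present |= tips_below(node)
    char = {t.label: int(t.label in present) for t in taxa}
    return tree, char, n_gains
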