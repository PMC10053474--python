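"""Synthetic screen generator.

Generates photometric tables with the statistical structure the analysis
assumes: per-channel baselines, per-library multipliers, multiplicative
planted motif effects, an optional property-coupled term and lognormal
spot noise.  The intensity of a spot carrying peptide p in channel c is

    I = baseline_c * lib_mult * prod(effect terms) * exp(beta * prop(p))
        * exp(N(0, sigma^2))

so log-intensity is additive and intensities are positive and
right-skewed, as fluorescence data are.  A planted effect multiplies the
intensity once per presence of its motif, or once per (overlapping)
occurrence with an optional saturation cap on the counted occurrences.

``preset_paperlike`` returns ready configurations emulating the two real
screens at order-of-magnitude fidelity: the AU screen (6-mers, 3 copies,
adenine channel far above uracil, saturating F/Y effects) and the GC
screen (7-mers, 2 copies, cytosine above guanine, dominant sublibrary
boosted, nested polyproline effects that saturate at run length 5, and an
alanine-at-position-4 bonus in the polyproline context).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import ArrayDesign, enumerate_library, layout_array, subset_library
from .properties import PropertyScale, load_scales, sum_property

PER_PRESENCE = "per_presence"
PER_OCCURRENCE = "per_occurrence"


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative motif effect in one channel.

    ``per_occurrence`` counts overlapping matches of the motif (optionally
    capped at ``saturation``) and applies ``multiplier**count``;
    ``per_presence`` applies the multiplier once if the motif occurs.
    """

    motif: str
    channel: str
    multiplier: float
    mode: str = PER_OCCURRENCE
    saturation: int | None = None


@dataclass(frozen=True)
class PropertyEffect:
    """Linear term on log-intensity: exp(coefficient * sum_property)."""

    scale: PropertyScale
    coefficient: float
    channel: str


@dataclass
class SimConfig:
    design: ArrayDesign
    baselines: dict[str, float]
    effects: list[PlantedEffect] = field(default_factory=list)
    library_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    property_effect: PropertyEffect | None = None
    sigma: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not self.baselines:
            raise ValueError("no channels configured")
        if any(b <= 0 for b in self.baselines.values()):
            raise ValueError("baselines must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        alphabet = set().union(*(set(p) for p in self.design.spots["peptide"].unique()))
        for eff in self.effects:
            if eff.multiplier <= 0:
                raise ValueError(f"effect {eff.motif}: multiplier must be > 0")
            if eff.mode not in (PER_PRESENCE, PER_OCCURRENCE):
                raise ValueError(f"effect {eff.motif}: unknown mode {eff.mode!r}")
            outside = set(eff.motif) - alphabet
            if outside:
                raise ValueError(
                    f"effect motif {eff.motif!r} uses residues {sorted(outside)} "
                    "outside the design alphabet"
                )


def _peptide_multipliers(config: SimConfig, channel: str, peptides: np.ndarray) -> np.ndarray:
    """Noise-free per-peptide effect product for one channel."""
    mult = np.ones(len(peptides))
    series = pd.Series(peptides)
    for eff in config.effects:
        if eff.channel != channel:
            continue
        if eff.mode == PER_PRESENCE:
            count = series.str.contains(eff.motif, regex=False).to_numpy().astype(int)
        else:
            pattern = f"(?={re.escape(eff.motif)})"
            count = series.str.count(pattern).to_numpy()
            if eff.saturation is not None:
                count = np.minimum(count, eff.saturation)
        mult *= eff.multiplier ** count
    pe = config.property_effect
    if pe is not None and pe.channel == channel:
        props = np.array([sum_property(p, pe.scale) for p in peptides])
        mult *= np.exp(pe.coefficient * props)
    return mult


def expected_intensity(config: SimConfig, peptide: str, library_id: str, channel: str) -> float:
    """Closed-form noise-free intensity of one peptide (sigma ignored)."""
    base = config.baselines[channel]
    base *= config.library_effects.get(library_id, {}).get(channel, 1.0)
    return float(base * _peptide_multipliers(config, channel, np.array([peptide]))[0])


def simulate_screen(config: SimConfig) -> pd.DataFrame:
    """Generate a long-form intensity table for every spot and channel.

    Deterministic for a given config and seed; readable back through
    ``read_photometric_table`` (long dialect).
    """
    config.validate()
    spots = config.design.spots
    peptides = pd.unique(spots["peptide"])
    rng = np.random.default_rng(config.seed)
    frames = []
    for channel in sorted(config.baselines):
        per_pep = dict(
            zip(peptides, _peptide_multipliers(config, channel, np.asarray(peptides)))
        )
        base = np.full(len(spots), config.baselines[channel])
        lib_mult = (
            spots["library_id"]
            .map(lambda lib: config.library_effects.get(lib, {}).get(channel, 1.0))
            .to_numpy()
        )
        pep_mult = spots["peptide"].map(per_pep).to_numpy()
        noise = (
            np.exp(rng.normal(0.0, config.sigma, len(spots)))
            if config.sigma > 0
            else 1.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "spot_id": spots["spot_id"],
                    "channel": channel,
                    "intensity": base * lib_mult * pep_mult * noise,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def preset_paperlike(
    which: str,
    seed: int = 0,
    channels: list[str] | None = None,
    n_peptides: int | None = None,
    copies: int | None = None,
    scan_bonus: bool = True,
    sigma: float = 0.3,
) -> SimConfig:
    """Ready-made configuration emulating one of the two real screens.

    ``which='AU'``: dominant (KFNIY, 5^6) and recessive (ELDVQH, 6^6)
    6-mer sublibraries subsampled to 23,403 peptides, 3 copies; adenine
    baseline ~19x the uracil baseline; saturating multiplicative F and Y
    effects in the adenine channel make F/Y-rich fragments the consistent
    bright signatures.

    ``which='GC'``: full dominant (GPAR) and recessive (STCR) 7-mer
    sublibraries, 2 copies; cytosine baseline ~2.2x guanine; the dominant
    sublibrary boosted 2.5x in the C channel; nested per-presence
    polyproline effects (PPP/PPPP/PPPPP) that add nothing beyond run
    length 5, plus (if ``scan_bonus``) a x6 bonus for the PPPAPPP context
    so a polyproline substitution scan recovers the position-4 alanine.

    Baseline magnitudes and ratios are order-of-magnitude emulations of
    the real screens' channel hierarchies, not fits to the deposited data.
    """
    if which == "AU":
        dom = enumerate_library(("K", "F", "N", "I", "Y"), 6, "AU-dominant", copies=3)
        rec = enumerate_library(("E", "L", "D", "V", "Q", "H"), 6, "AU-recessive", copies=3)
        n_total = 23_403 if n_peptides is None else n_peptides
        if n_total < len(dom) + len(rec):
            n_dom = max(1, round(n_total * len(dom) / (len(dom) + len(rec))))
            dom = subset_library(dom, n_dom, seed=seed * 2 + 1)
            rec = subset_library(rec, n_total - n_dom, seed=seed * 2 + 2)
        design = layout_array([dom, rec], seed=seed, copies=None if copies is None else {dom.library_id: copies, rec.library_id: copies})
        baselines = {"A12": 1150.0, "U12": 60.0}
        effects = [
            PlantedEffect("F", "A12", 1.6, PER_OCCURRENCE, saturation=2),
            PlantedEffect("Y", "A12", 1.5, PER_OCCURRENCE, saturation=2),
        ]
        library_effects = {"AU-dominant": {"U12": 0.92}}
    elif which == "GC":
        dom = enumerate_library(("G", "P", "A", "R"), 7, "GC-dominant", copies=2)
        rec = enumerate_library(("S", "T", "C", "R"), 7, "GC-recessive", copies=2)
        if n_peptides is not None:
            dom = subset_library(dom, min(n_peptides, len(dom)), seed=seed * 2 + 1)
            rec = subset_library(rec, min(n_peptides, len(rec)), seed=seed * 2 + 2)
        design = layout_array([dom, rec], seed=seed, copies=None if copies is None else {dom.library_id: copies, rec.library_id: copies})
        baselines = {"C12": 1250.0, "G12": 560.0}
        effects = [
            PlantedEffect("PPP", "C12", 4.0, PER_PRESENCE),
            PlantedEffect("PPPP", "C12", 1.15, PER_PRESENCE),
            PlantedEffect("PPPPP", "C12", 1.1, PER_PRESENCE),
        ]
        if scan_bonus:
            effects.append(PlantedEffect("PPPAPPP", "C12", 6.0, PER_PRESENCE))
        library_effects = {"GC-dominant": {"C12": 2.5, "G12": 1.2}}
    else:
        raise ValueError(f"unknown preset {which!r}; expected 'AU' or 'GC'")
    if channels is not None:
        unknown = set(channels) - set(baselines)
        if unknown:
            raise ValueError(f"preset {which} has no channels {sorted(unknown)}")
        baselines = {c: b for c, b in baselines.items() if c in channels}
    return SimConfig(
        design=design,
        baselines=baselines,
        effects=effects,
        library_effects=library_effects,
        sigma=sigma,
        seed=seed,
    )


def charge_penalty_effect(coefficient: float, channel: str) -> PropertyEffect:
    """Convenience: couple log-intensity to the sum charge of the peptide."""
    return PropertyEffect(scale=load_scales()["charge"], coefficient=coefficient, channel=channel)
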