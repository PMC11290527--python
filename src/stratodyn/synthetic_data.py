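"""Synthetic fossil / rock / surface / geochemical datasets with known truth.

The generator emulates the statistical structure the analysis assumes — it
is a study-condition simulator, not a reconstruction of any real region:

* **Occurrences** — taxa clustered into the four successive assemblages
  (Avalon, White Sea, Nama, Cambrian), each taxon with a true range drawn
  as (origin uniform in the assemblage window, duration exponential
  truncated to the window; the simplest right-skewed range model).  The
  default taxon budget is 332 genera split 27/30/24/251 across the
  assemblages (81 Ediacaran + 251 Cambrian).  Reported occurrence bounds
  widen the true endpoint ages symmetrically by a category-specific
  half-width (0 / 0.5 / 1.5 / 3.0 Ma for categories 1–4).  A category-1
  taxon is emitted as one record carrying its full true range; categories
  2–4 are emitted as two endpoint occurrence records (a FAD occurrence and
  a LAD occurrence), each carrying its own permitted interval, so that
  occurrence-level resampling and the envelope rule are exercised the way
  the analysis applies them.
* **Rock units** — per region, a stack of non-overlapping units built old →
  young, with hiatuses inserted at a configurable probability and
  lithofacies drawn from the class taxonomy; every unit carries its
  region's constant terrane area (presence/absence area logic).
* **Surfaces** — one fossiliferous surface per body-fossil occurrence
  record (well constrained for categories 1–2, uncertain for 3–4), so
  sampling intensity co-varies with the fossil record.
* **Geochemistry** — a smooth latent δ¹³C curve (sum of sinusoids) plus an
  antithetic δ²³⁸U latent built to a target anticorrelation, with additive
  noise and irregular sample ages; a stated fraction of samples carries
  both isotopes (``paired``).

All randomness flows from ``master_seed`` through named
:class:`numpy.random.SeedSequence` streams (child 0: occurrences, child 1:
rock record, child 2: geochemistry, child 3: surfaces), so every product is
reproducible and the streams are independent.

All distributions here are configurable stand-ins: no public distributional
facts exist for the underlying databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity_dynamics
from .data_model_io import (
    DEPTH_BEARING_GROUPS,
    NONMARINE_GROUPS,
    TimeGrid,
    validate_table,
    write_table,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_occurrences",
    "generate_rock_record",
    "generate_surfaces",
    "generate_geochem",
    "write_dataset",
]


def _default_regions() -> dict[str, float]:
    # 24 composite regions; terrane areas log-spaced over a realistic
    # 1e4 - 1e6 km^2 span
    areas = np.logspace(4, 6, 24)
    return {f"region_{i + 1:02d}": float(round(a, 1)) for i, a in enumerate(areas)}


_DEFAULT_AFFINITY_WEIGHTS = {
    # dominant sedimentary settings per assemblage
    "Avalon": {"deep_siliciclastic": 0.75, "shallow_mid_siliciclastic": 0.25},
    "WhiteSea": {"shallow_mid_siliciclastic": 0.9, "deep_siliciclastic": 0.1},
    "Nama": {
        "shallow_mid_siliciclastic": 0.35,
        "shallow_mid_limestone": 0.45,
        "shallow_mid_dolostone": 0.2,
    },
    "Cambrian": {
        "shallow_mid_limestone": 0.55,
        "shallow_mid_dolostone": 0.25,
        "shallow_mid_siliciclastic": 0.2,
    },
}

_DEFAULT_GROUP_WEIGHTS = {
    "siliciclastic": 0.45,
    "limestone": 0.22,
    "dolostone": 0.13,
    "phosphorite": 0.04,
    "diamictite": 0.03,
    "evaporitic_semirestricted": 0.06,
    "fluvial_subaerial": 0.04,
    "volcanic": 0.03,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic datasets (see module docstring)."""

    n_taxa: dict[str, int] = field(
        default_factory=lambda: {"Avalon": 27, "WhiteSea": 30, "Nama": 24, "Cambrian": 251}
    )
    assemblage_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Avalon": (575.0, 559.0),
            "WhiteSea": (560.0, 550.0),
            "Nama": (550.5, 538.0),
            "Cambrian": (535.0, 522.0),
        }
    )
    uncertainty_mixture: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.35, 3: 0.25, 4: 0.15}
    )
    uncertainty_half_width: dict[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 0.5, 3: 1.5, 4: 3.0}
    )
    affinity_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_AFFINITY_WEIGHTS.items()}
    )
    mean_taxon_duration: float = 4.0  # Ma, exponential mean before truncation

    regions: dict[str, float] = field(default_factory=_default_regions)
    group_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_WEIGHTS)
    )
    mean_unit_thickness_m: float = 200.0
    thickness_sigma: float = 0.7  # lognormal shape
    mean_unit_duration: float = 2.0  # Ma
    hiatus_probability: float = 0.3
    mean_hiatus_duration: float = 1.5  # Ma

    n_geochem: int = 900
    geochem_noise_sd_c: float = 0.5  # permil, d13C
    geochem_noise_sd_u: float = 0.05  # permil, d238U
    target_anticorrelation: float = -0.7
    paired_fraction: float = 0.35

    # extra occurrence rows exercising the diversity-filter toggles
    n_trace: int = 8
    n_holdfast_only: int = 5
    n_excluded_taxa: int = 3
    n_lagerstatte: int = 5

    grid: TimeGrid = field(default_factory=TimeGrid)
    master_seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.uncertainty_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("uncertainty_mixture probabilities must sum to 1")
        if any(w < 0 for w in self.uncertainty_half_width.values()):
            raise ValueError("uncertainty half-widths must be >= 0")
        if not -1.0 <= self.target_anticorrelation <= 0.0:
            raise ValueError("target_anticorrelation must lie in [-1, 0]")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must lie in [0, 1]")
        if not 0.0 <= self.hiatus_probability <= 1.0:
            raise ValueError("hiatus_probability must lie in [0, 1]")
        for a, (older, younger) in self.assemblage_windows.items():
            if older <= younger:
                raise ValueError(f"assemblage {a}: window must be (older, younger)")

    def streams(self) -> dict[str, np.random.SeedSequence]:
        kids = np.random.SeedSequence(self.master_seed).spawn(4)
        return {
            "occurrences": kids[0],
            "rock": kids[1],
            "geochem": kids[2],
            "surfaces": kids[3],
        }


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic occurrence table."""

    true_ranges: pd.DataFrame  # genus, assemblage, affinity, region, fad, lad
    latent_geochem: pd.DataFrame | None = None
    seeds: dict = field(default_factory=dict)

    def true_richness(self, windows: pd.DataFrame) -> np.ndarray:
        """Per-window richness recomputed exactly from the true ranges."""
        return diversity_dynamics.richness_per_window(self.true_ranges, windows)


def generate_occurrences(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Occurrence table plus truth record (see module docstring for the model)."""
    config.validate()
    rng = np.random.default_rng(config.streams()["occurrences"])
    region_names = sorted(config.regions)
    cats = np.array(sorted(config.uncertainty_mixture))
    cat_p = np.array([config.uncertainty_mixture[c] for c in cats])

    truth_rows = []
    occ_rows = []
    no_taxa = sum(config.n_taxa.values()) == 0
    for assemblage in sorted(config.n_taxa):
        n = config.n_taxa[assemblage]
        if n == 0:
            continue
        older, younger = config.assemblage_windows[assemblage]
        aff_w = config.affinity_weights[assemblage]
        aff_names = sorted(aff_w)
        aff_p = np.array([aff_w[a] for a in aff_names])
        aff_p = aff_p / aff_p.sum()
        for i in range(n):
            genus = f"{assemblage}_taxon_{i + 1:03d}"
            origin = rng.uniform(younger, older)
            duration = min(rng.exponential(config.mean_taxon_duration), origin - younger)
            fad, lad = origin, origin - duration
            cat = int(rng.choice(cats, p=cat_p))
            affinity = str(rng.choice(aff_names, p=aff_p))
            region = str(rng.choice(region_names))
            truth_rows.append(
                {"genus": genus, "assemblage": assemblage, "lithology_affinity": affinity,
                 "region": region, "fad": fad, "lad": lad,
                 "uncertainty_category": cat}
            )
            base = {
                "region": region, "uncertainty_category": cat,
                "lithology_affinity": affinity, "assemblage": assemblage,
                "record_class": "body", "lagerstatte": False, "genus": genus,
            }
            h = config.uncertainty_half_width[cat]
            if cat == 1:
                occ_rows.append({**base, "max_age": fad, "min_age": lad})
            else:
                # endpoint occurrences with symmetric permitted intervals
                occ_rows.append(
                    {**base, "max_age": fad + h, "min_age": max(fad - h, 1e-6)}
                )
                occ_rows.append(
                    {**base, "max_age": lad + h, "min_age": max(lad - h, 1e-6)}
                )

    # extra records exercising the diversity filters (not part of the truth)
    def _extra(n, record_class, lagerstatte, prefix):
        for j in range(n):
            older, younger = config.grid.oldest, config.grid.youngest
            a = rng.uniform(younger + 1.0, older - 1.0)
            occ_rows.append(
                {
                    "genus": f"{prefix}_{j + 1:02d}",
                    "region": str(rng.choice(region_names)),
                    "max_age": a + 1.0,
                    "min_age": a,
                    "uncertainty_category": int(rng.choice(cats, p=cat_p)),
                    "lithology_affinity": "shallow_mid_siliciclastic",
                    "assemblage": "Cambrian" if a < 538.8 else "Nama",
                    "record_class": record_class,
                    "lagerstatte": lagerstatte,
                }
            )

    if not no_taxa:  # zero taxa requested -> empty collection, empty truth
        _extra(config.n_trace, "trace", False, "trace")
        _extra(config.n_holdfast_only, "holdfast_only", False, "holdfast")
        _extra(config.n_excluded_taxa, "excluded_taxon", False, "excluded")
        _extra(config.n_lagerstatte, "body", True, "lagerstatte")

    columns = ["genus", "region", "max_age", "min_age", "uncertainty_category",
               "lithology_affinity", "assemblage", "record_class", "lagerstatte"]
    occ = pd.DataFrame(occ_rows, columns=columns) if occ_rows else pd.DataFrame(
        columns=columns
    )
    if not occ.empty:
        occ = validate_table(occ, "occurrences")
    truth_cols = ["genus", "assemblage", "lithology_affinity", "region",
                  "fad", "lad", "uncertainty_category"]
    truth = SyntheticTruth(
        true_ranges=pd.DataFrame(truth_rows, columns=truth_cols),
        seeds={"master_seed": config.master_seed},
    )
    return occ, truth


def _draw_lithofacies(rng, config) -> tuple[str, str, bool]:
    groups = sorted(config.group_weights)
    p = np.array([config.group_weights[g] for g in groups])
    group = str(rng.choice(groups, p=p / p.sum()))
    if group in DEPTH_BEARING_GROUPS:
        depth = str(
            rng.choice(
                ["shallow_inner_shelf", "mid_outer_shelf_upper_slope", "lower_slope_basinal"],
                p=[0.5, 0.35, 0.15],
            )
        )
    else:
        depth = "not_applicable"
    marine = group not in NONMARINE_GROUPS
    return group, depth, marine


def generate_rock_record(config: SyntheticConfig) -> pd.DataFrame:
    """Per-region stacks of non-overlapping units with hiatuses."""
    config.validate()
    rng = np.random.default_rng(config.streams()["rock"])
    oldest, youngest = config.grid.oldest, config.grid.youngest
    rows = []
    for region in sorted(config.regions):
        area = config.regions[region]
        t = oldest
        i = 0
        while t > youngest:
            if config.hiatus_probability >= 1.0 or (
                config.hiatus_probability > 0.0
                and rng.random() < config.hiatus_probability
            ):
                gap = max(rng.exponential(config.mean_hiatus_duration), 0.05)
                t -= gap
                continue
            dur = min(max(rng.exponential(config.mean_unit_duration), 0.1), t - youngest)
            group, depth, marine = _draw_lithofacies(rng, config)
            thickness = rng.lognormal(
                np.log(config.mean_unit_thickness_m), config.thickness_sigma
            )
            i += 1
            rows.append(
                {
                    "region": region,
                    "unit_id": f"{region}_u{i:03d}",
                    "group": group,
                    "depth": depth,
                    "marine": marine,
                    "mean_thickness": thickness,
                    "area": area,
                    "base_age": t,
                    "top_age": t - dur,
                }
            )
            t -= dur
    columns = ["region", "unit_id", "group", "depth", "marine",
               "mean_thickness", "area", "base_age", "top_age"]
    units = pd.DataFrame(rows, columns=columns)
    if not units.empty:
        units = validate_table(units, "rock_units")
    return units


def generate_surfaces(config: SyntheticConfig, occurrences: pd.DataFrame) -> pd.DataFrame:
    """One fossiliferous surface per body-fossil occurrence record.

    Categories 1–2 map to well-constrained surfaces; 3–4 to uncertain ones.
    Trace-fossil rows produce no surface (intensity counts body records,
    including holdfasts and excluded taxa).
    """
    config.validate()
    body = occurrences[occurrences["record_class"] != "trace"].reset_index(drop=True)
    quality = np.where(
        body["uncertainty_category"] <= 2, "well_constrained", "uncertain"
    )
    surfaces = pd.DataFrame(
        {
            "surface_id": [f"surf_{i + 1:04d}" for i in range(len(body))],
            "region": body["region"],
            "max_age": body["max_age"],
            "min_age": body["min_age"],
            "constraint_quality": quality,
        }
    )
    if not surfaces.empty:
        surfaces = validate_table(surfaces, "surfaces")
    return surfaces


def _latent_curves(ages: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two independent smooth standardized curves over the age span."""
    phases = rng.uniform(0, 2 * np.pi, size=6)

    def curve(periods, p0, p1, p2):
        c = (
            np.sin(2 * np.pi * ages / periods[0] + p0)
            + 0.7 * np.sin(2 * np.pi * ages / periods[1] + p1)
            + 0.4 * np.sin(2 * np.pi * ages / periods[2] + p2)
        )
        return (c - c.mean()) / c.std()

    # distinct period sets keep the two latents close to uncorrelated
    return (
        curve((34.0, 13.0, 5.5), *phases[:3]),
        curve((23.0, 9.0, 4.1), *phases[3:]),
    )


def generate_geochem(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Irregularly sampled, noisy, antithetic δ¹³C / δ²³⁸U series.

    Returns ``(samples, latent)`` where *latent* holds the noise-free
    per-sample curves (part of the truth record).
    """
    config.validate()
    rng = np.random.default_rng(config.streams()["geochem"])
    ages = np.sort(rng.uniform(config.grid.youngest, config.grid.oldest, config.n_geochem))[::-1]
    z_c, z_e = _latent_curves(ages, rng)
    a = abs(config.target_anticorrelation)
    z_u = a * (-z_c) + np.sqrt(max(0.0, 1.0 - a * a)) * z_e
    latent_c = 1.0 + 3.0 * z_c  # permil VPDB, amplitude ~ observed excursions
    latent_u = -0.45 + 0.20 * z_u  # permil, baseline near modern-ish values
    c_obs = latent_c + rng.normal(0.0, config.geochem_noise_sd_c, ages.size)
    u_obs = latent_u + rng.normal(0.0, config.geochem_noise_sd_u, ages.size)

    paired = rng.random(ages.size) < config.paired_fraction
    only_c = ~paired & (rng.random(ages.size) < 0.5)
    d13c = np.where(paired | only_c, c_obs, np.nan)
    d238u = np.where(paired | ~only_c, u_obs, np.nan)
    samples = pd.DataFrame(
        {
            "age": ages,
            "d13C": d13c,
            "d238U": d238u,
            "provenance": "synthetic",
            "paired": paired,
        }
    )
    samples = validate_table(samples, "geochem")
    latent = pd.DataFrame({"age": ages, "d13C_latent": latent_c, "d238U_latent": latent_u})
    return samples, latent


def write_dataset(config: SyntheticConfig, out_dir) -> dict[str, Path]:
    """Generate and write the four input tables plus the truth file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    occ, truth = generate_occurrences(config)
    units = generate_rock_record(config)
    surfaces = generate_surfaces(config, occ)
    geochem, latent = generate_geochem(config)
    truth.latent_geochem = latent
    paths = {
        "occurrences": out / "occurrences.tsv",
        "rock_units": out / "rock_units.tsv",
        "surfaces": out / "surfaces.tsv",
        "geochem": out / "geochem.tsv",
        "truth_ranges": out / "truth_ranges.tsv",
        "truth_geochem": out / "truth_geochem.tsv",
    }
    write_table(occ, paths["occurrences"])
    write_table(units, paths["rock_units"])
    write_table(surfaces, paths["surfaces"])
    write_table(geochem, paths["geochem"])
    write_table(truth.true_ranges, paths["truth_ranges"])
    write_table(latent, paths["truth_geochem"])
    return paths
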