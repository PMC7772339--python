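"""Synthetic peatland moss-microbiome study generator.

Emulates the sampling design of a two-system peatland survey: brown-moss
(Amblystegiaceae, ``amb``) fens with sub-neutral pH versus acidic
*Sphagnum* (``sph``) bogs, each system represented by several areas,
areas by subsites, subsites by moss plants. Every moss plant yields two
endophyte technical-replicate libraries (surface-sterilized tissue) and
one epiphyte library (wash-off), and every subsite contributes reference
libraries (sediment and vascular plants).

Planted ground truth makes downstream answers recoverable:

* a shared core of OTUs abundant in every moss sample of both systems
  (weights chosen so that the core dominates *Sphagnum* communities and is
  a minor but consistent component of Amblystegiaceae ones),
* system-specific OTU blocks (near-zero expected abundance outside their
  system),
* endophyte-enriched OTUs whose expected abundance is multiplied by a fold
  factor in endophyte fractions only,
* continuous covariates (pH, temperature, CH4) correlated with the system
  partition by construction, driving log-linear composition shifts.

Counts are Dirichlet-multinomial: expected proportions from the log-linear
model, a plant-level Dirichlet draw shared by the libraries of one plant,
small replicate-level jitter for technical replicates, and multinomial
sampling at a uniform-random library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .community_data import OtuTable

__all__ = [
    "StudyConfig",
    "SyntheticTruth",
    "generate_study",
    "truth_recovery_report",
]

_AREA_LABELS = {"amb": ["SV", "SA", "A3", "A4"], "sph": ["NEI", "MUE", "S3", "S4"]}
_SPECIES = {
    "amb": ["Scorpidium", "Amb_mix", "Meesia", "Drepanocladus"],
    "sph": ["S_riparium", "S_fallax", "S_magellanicum", "S_lindbergii"],
}
# pH ranges observed in the two peatland types (sub-neutral fens vs acid bogs)
_PH_RANGE = {"amb": (5.8, 7.0), "sph": (3.3, 5.0)}
_TEMP_RANGE = {"amb": (4.0, 13.0), "sph": (10.0, 17.6)}
_CH4_RANGE = {"amb": (0.0, 124.0), "sph": (21.8, 948.0)}


@dataclass(frozen=True)
class StudyConfig:
    """Design and effect sizes of a synthetic study.

    Defaults mirror the emulated survey: 2 systems x 2 areas x 3 subsites
    x 3 moss plants (3 libraries each) plus 2 references per subsite, 2000
    OTUs of which 50 shared core, 300 per-system specific and 25
    endophyte-enriched. ``core_mean_relabund`` is the per-OTU expected
    weight relative to a unit-mass background community, so 50 core OTUs
    at 0.02 make the core roughly half of a *Sphagnum* community while 50
    at 0.002 keep it below ten percent in Amblystegiaceae — matching the
    asymmetric core contributions the design emulates.
    """

    n_areas_per_system: int = 2
    n_subsites_per_area: int = 3
    n_plants_per_subsite: int = 3
    n_reference_samples_per_subsite: int = 2
    n_otus_total: int = 2000
    n_core_shared: int = 50
    n_system_specific_per_system: int = 300
    n_endophyte_enriched: int = 25
    core_mean_relabund_sph: float = 0.02
    core_mean_relabund_amb: float = 0.002
    endophyte_fold: float = 8.0
    #: mean log-weight of planted endophyte OTUs (background OTUs are
    #: N(0, 1.2) on the same scale), placing them in the abundant tail
    endophyte_base_logabund: float = 2.5
    library_size_range: tuple[int, int] = (5_000, 50_000)
    dispersion: float = 200.0
    replicate_dispersion: float = 1e6
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"pH": 1.0, "temperature": 0.5, "ch4": 0.5}
    )
    plant_species_effect: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_core_shared + 2 * self.n_system_specific_per_system > self.n_otus_total:
            raise ValueError("planted OTU sets exceed n_otus_total")
        planted = (
            self.n_core_shared
            + 2 * self.n_system_specific_per_system
            + self.n_endophyte_enriched
        )
        if planted > self.n_otus_total:
            raise ValueError("planted OTU sets exceed n_otus_total")
        if self.endophyte_fold < 1:
            raise ValueError("endophyte_fold must be >= 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_size_range")
        for f in (
            "n_areas_per_system",
            "n_subsites_per_area",
            "n_plants_per_subsite",
            "n_otus_total",
        ):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_effects"] = dict(self.covariate_effects)
        d["library_size_range"] = list(self.library_size_range)
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated study."""

    planted_core_ids: tuple[str, ...]
    planted_system_specific_ids: dict[str, tuple[str, ...]]
    planted_endophyte_ids: tuple[str, ...]
    expected_composition: pd.DataFrame  # OTUs x samples expected proportions
    covariates: pd.DataFrame  # per-sample covariate values


def _uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return lo + (hi - lo) * rng.random(n)


def generate_study(config: StudyConfig) -> tuple[OtuTable, pd.DataFrame, SyntheticTruth]:
    """Generate (OtuTable, metadata DataFrame, SyntheticTruth).

    Deterministic under ``config.seed``. See the module docstring for the
    composition model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_otus_total
    otu_ids = tuple(f"OTU_{i:05d}" for i in range(n))
    ids = np.arange(n)
    core = ids[: config.n_core_shared]
    spec_amb = ids[config.n_core_shared : config.n_core_shared + config.n_system_specific_per_system]
    spec_sph = ids[
        config.n_core_shared
        + config.n_system_specific_per_system : config.n_core_shared
        + 2 * config.n_system_specific_per_system
    ]
    endo = ids[
        config.n_core_shared
        + 2 * config.n_system_specific_per_system : config.n_core_shared
        + 2 * config.n_system_specific_per_system
        + config.n_endophyte_enriched
    ]
    taxonomy = _make_taxonomy(rng, n, core, spec_amb, spec_sph)

    # background log-weights; system-specific OTUs suppressed off-system
    base_logw = rng.normal(0.0, 1.2, size=n)
    # planted endophyte OTUs come from the abundant tail: their epiphyte
    # baseline must clear the screen's relative-abundance floor once
    # multiplied by the enrichment fold, or the planted set would be
    # structurally unrecoverable
    base_logw[endo] = rng.normal(config.endophyte_base_logabund, 0.4, size=endo.size)
    # per-covariate sparse OTU sensitivities
    cov_sens = {}
    for var, slope in config.covariate_effects.items():
        s = np.zeros(n)
        responders = rng.choice(n, size=max(1, n // 10), replace=False)
        s[responders] = rng.normal(0.0, 1.0, size=len(responders))
        cov_sens[var] = s * slope
    # plant-species effects: per-species sparse log shifts
    species_shift: dict[str, np.ndarray] = {}

    samples: list[dict] = []
    comps: list[np.ndarray] = []
    counts_cols: list[np.ndarray] = []

    def expected_profile(system: str, species: str, cov: dict, endo_frac: bool) -> np.ndarray:
        logw = base_logw.copy()
        off = spec_sph if system == "amb" else spec_amb
        on = spec_amb if system == "amb" else spec_sph
        logw[off] = -np.inf  # system-specific OTUs absent off-system
        logw[on] += 1.0
        if species not in species_shift:
            s = np.zeros(n)
            responders = rng.choice(n, size=max(1, n // 20), replace=False)
            s[responders] = rng.normal(0.0, 1.0, size=len(responders))
            species_shift[species] = s * config.plant_species_effect
        logw = logw + species_shift[species]
        for var, sens in cov_sens.items():
            lo, hi = {"pH": (3.3, 7.0), "temperature": (2.0, 20.7), "ch4": (0.0, 948.0)}[var]
            z = (cov[var] - (lo + hi) / 2) / ((hi - lo) / 2 or 1.0)
            logw = logw + sens * z
        if endo_frac and config.endophyte_fold > 1:
            logw[endo] += np.log(config.endophyte_fold)
        w = np.exp(logw - np.nanmax(logw[np.isfinite(logw)]))
        w[~np.isfinite(w)] = 0.0
        w /= w.sum()
        # overlay the planted core at a fixed weight relative to unit background
        core_w = (
            config.core_mean_relabund_sph if system == "sph" else config.core_mean_relabund_amb
        )
        w[core] = 0.0
        w /= w.sum()
        w = w * 1.0  # background mass 1
        w[core] = core_w
        return w / w.sum()

    lo, hi = config.library_size_range
    for si, system in enumerate(("amb", "sph")):
        areas = _AREA_LABELS[system][: config.n_areas_per_system]
        species_pool = _SPECIES[system]
        for ai, area in enumerate(areas):
            area_temp = _uniform(rng, *_TEMP_RANGE[system], 1)[0]
            for sub in range(config.n_subsites_per_area):
                subsite = f"{area}{sub + 1}"
                hydrology_site = "submerged" if rng.random() < 0.4 else "emerged"
                ph_site = _uniform(rng, *_PH_RANGE[system], 1)[0]
                ch4_site = _uniform(rng, *_CH4_RANGE[system], 1)[0]
                for p in range(config.n_plants_per_subsite):
                    species = species_pool[(ai + p) % len(species_pool)]
                    unit = f"{subsite}_P{p + 1}"
                    cov = {
                        "pH": ph_site + rng.normal(0, 0.1),
                        "temperature": area_temp + rng.normal(0, 1.0),
                        "ch4": max(0.0, ch4_site * np.exp(rng.normal(0, 0.2))),
                    }
                    prof_endo = expected_profile(system, species, cov, endo_frac=True)
                    prof_epi = expected_profile(system, species, cov, endo_frac=False)
                    # one plant-level latent composition shared by all three
                    # libraries of the plant; the endophyte version reweights
                    # the *same* latent by the enrichment fold, so that with
                    # fold = 1 the endo and epi libraries are exchangeable
                    # draws (a recoverable null for the paired screen)
                    latent_epi = rng.dirichlet(np.maximum(prof_epi * config.dispersion, 1e-12))
                    latent_endo = latent_epi.copy()
                    if config.endophyte_fold > 1:
                        latent_endo[endo] *= config.endophyte_fold
                        latent_endo = latent_endo / latent_endo.sum()
                    for rep, (frac, latent, prof) in enumerate(
                        [
                            ("endophyte", latent_endo, prof_endo),
                            ("endophyte", latent_endo, prof_endo),
                            ("epiphyte", latent_epi, prof_epi),
                        ]
                    ):
                        sid = f"{unit}_{'endo' + str(rep + 1) if frac == 'endophyte' else 'epi'}"
                        jitter = rng.dirichlet(
                            np.maximum(latent * config.replicate_dispersion, 1e-12)
                        )
                        size = int(rng.integers(lo, hi + 1))
                        counts_cols.append(rng.multinomial(size, jitter))
                        comps.append(prof)
                        samples.append(
                            dict(
                                sample_id=sid,
                                system=system,
                                area=area,
                                subsite=subsite,
                                plant_label=species,
                                sample_class="moss",
                                fraction=frac,
                                plant_unit=unit,
                                hydrology=hydrology_site,
                                pH=round(cov["pH"], 2),
                                temperature=round(cov["temperature"], 1),
                                ch4=round(cov["ch4"], 1),
                            )
                        )
                for r in range(config.n_reference_samples_per_subsite):
                    ref_class = "sediment" if r % 2 == 0 else "vascular"
                    label = "sediment" if ref_class == "sediment" else "Vasc_mix"
                    cov = {
                        "pH": ph_site + rng.normal(0, 0.1),
                        "temperature": area_temp + rng.normal(0, 1.0),
                        "ch4": max(0.0, ch4_site * np.exp(rng.normal(0, 0.2))),
                    }
                    prof = expected_profile(system, label, cov, endo_frac=False)
                    latent = rng.dirichlet(np.maximum(prof * config.dispersion, 1e-12))
                    size = int(rng.integers(lo, hi + 1))
                    counts_cols.append(rng.multinomial(size, latent))
                    comps.append(prof)
                    samples.append(
                        dict(
                            sample_id=f"{subsite}_{ref_class}{r + 1}",
                            system=system,
                            area=area,
                            subsite=subsite,
                            plant_label=label,
                            sample_class=ref_class,
                            fraction="reference",
                            plant_unit="",
                            hydrology=hydrology_site,
                            pH=round(cov["pH"], 2),
                            temperature=round(cov["temperature"], 1),
                            ch4=round(cov["ch4"], 1),
                        )
                    )

    metadata = pd.DataFrame(samples).set_index("sample_id")
    counts = np.column_stack(counts_cols)
    sample_ids = tuple(metadata.index)
    table = OtuTable(
        otu_ids=otu_ids,
        sample_ids=sample_ids,
        counts=counts,
        taxonomy=taxonomy,
        domain_label="bacteria",
    )
    truth = SyntheticTruth(
        planted_core_ids=tuple(otu_ids[i] for i in core),
        planted_system_specific_ids={
            "amb": tuple(otu_ids[i] for i in spec_amb),
            "sph": tuple(otu_ids[i] for i in spec_sph),
        },
        planted_endophyte_ids=tuple(otu_ids[i] for i in endo),
        expected_composition=pd.DataFrame(
            np.column_stack(comps), index=list(otu_ids), columns=list(sample_ids)
        ),
        covariates=metadata[["pH", "temperature", "ch4"]].copy(),
    )
    return table, metadata, truth


def _make_taxonomy(rng, n, core, spec_amb, spec_sph) -> tuple[str, ...]:
    families = [
        "Acetobacteraceae",
        "Acidobacteriaceae",
        "Sphingomonadaceae",
        "Comamonadaceae",
        "Hyphomicrobiaceae",
        "Methylocystaceae",
        "Pseudanabaenaceae",
    ]
    tax = []
    for i in range(n):
        fam = families[int(rng.integers(len(families)))]
        tax.append(
            f"k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; "
            f"o__Rhizobiales; f__{fam}; g__; s__"
        )
    return tuple(tax)


def truth_recovery_report(
    truth: SyntheticTruth,
    core_ids: set[str] | None = None,
    endophyte_ids: set[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Sensitivity and false-discovery proportion of recovered OTU sets
    against the planted truth.

    ``core_ids`` / ``endophyte_ids`` are the OTU ids a downstream stage
    reported; either may be omitted. Returns, per evaluated set,
    ``{"sensitivity": ..., "fdp": ..., "n_called": ..., "n_planted": ...}``.
    """
    universe = set(truth.expected_composition.index)
    report: dict[str, dict[str, float]] = {}
    for name, called, planted in [
        ("core", core_ids, set(truth.planted_core_ids)),
        ("endophyte", endophyte_ids, set(truth.planted_endophyte_ids)),
    ]:
        if called is None:
            continue
        called = set(called)
        if not called <= universe:
            raise ValueError(
                f"{name}: called ids outside the study's OTU universe: "
                f"{sorted(called - universe)[:5]}"
            )
        tp = len(called & planted)
        report[name] = {
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "fdp": (len(called) - tp) / len(called) if called else 0.0,
            "n_called": float(len(called)),
            "n_planted": float(len(planted)),
        }
    return report
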