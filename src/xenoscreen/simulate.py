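"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates the structure of the corresponding experiment —
96-well screening plates with eight interspersed vehicle controls and a dye
footprint well, hourly 24-h logistic growth curves started at OD 0.05 with
multiplicative lognormal noise, two-fold dose-response series, arrayed
mutant plates, negative-binomial barcoded-insertion counts, abstract binary
fingerprints with a planted structure-activity rule, and Dirichlet-
multinomial community profiles — and returns the planted ground truth
alongside the emitted tables, so recovery, calibration and false-positive
behaviour of every downstream stage can be measured exactly.

All generators are pure functions of their configuration: a fixed seed
reproduces the output bit-for-bit, and each generator draws from its own
seed substream so adding one does not perturb the others.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthCurve, logistic_od
from .io import PlateMap, WellEntry
from .tnseq import InsertionCountTable
from .community import CommunityProfile

__all__ = [
    "SimulationConfig",
    "TnseqConfig",
    "MLConfig",
    "CommunityConfig",
    "GroundTruth",
    "gen_screen",
    "gen_dose_response",
    "gen_arrayed",
    "gen_tnseq",
    "gen_compound_library",
    "gen_community",
]

# fixed substream keys so each generator has an independent stream
_STREAMS = {"screen": 1, "dose": 2, "tnseq": 3, "library": 4, "community": 5, "arrayed": 6}

_ROWS = string.ascii_uppercase[:8]
# eight vehicle-control wells interspersed across the plate, plus one dye
# footprint well, mirroring the screening layout
_CONTROL_WELLS = ("A04", "B09", "C02", "D07", "E12", "F05", "G10", "H03")
_DYE_WELL = "H12"


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class TnseqConfig:
    """Pooled-library simulation settings.

    The study design is a condition arm vs a vehicle/media control arm with
    few biological replicates; counts are overdispersed (negative binomial)
    and planted per-gene fitness scales the condition-arm means by
    2^log2fc.
    """

    n_genes: int = 3000
    sites_per_gene: int = 10
    dispersion: float = 0.2
    n_cond: int = 2
    n_ctrl: int = 3
    n_planted: int = 20
    planted_log2fc: float = -3.0
    doublings_cond: float = 6.0
    doublings_ctrl: float = 6.0
    mean_count: float = 50.0


@dataclass(frozen=True)
class MLConfig:
    """Compound-library simulation: abstract fingerprints + planted rule."""

    n_compounds: int = 800
    n_features: int = 128
    embedding_dim: int = 768
    rule_bits: tuple[int, ...] = (7, 13)
    prevalence: float = 0.15
    label_noise: float = 0.0
    background_density: float = 0.1


@dataclass(frozen=True)
class CommunityConfig:
    """20-member community simulation with planted per-species sensitivity."""

    n_species: int = 20
    depth: int = 50000
    n_replicates: int = 3
    od_control: float = 0.8
    noise_cv: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Master configuration; defaults mirror the screening study design.

    22 strains x 3 biological replicates at a single 20 uM dose, hourly
    OD600 reads for 24 h starting at OD 0.05, 5% multiplicative noise, and
    a 50-95% AUC-reduction range for planted inhibitory interactions.
    """

    seed: int = 0
    n_compounds: int = 1076
    n_strains: int = 22
    n_replicates: int = 3
    hit_fraction: float = 0.1
    effect_size_range: tuple[float, float] = (0.5, 0.95)
    noise_cv: float = 0.05
    edge_effect_amplitude: float = 0.0
    dose_um: float = 20.0
    start_od: float = 0.05
    n_hours: int = 24
    tnseq: TnseqConfig = field(default_factory=TnseqConfig)
    ml: MLConfig = field(default_factory=MLConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)

    def __post_init__(self) -> None:
        for name in ("hit_fraction", "noise_cv", "edge_effect_amplitude"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.effect_size_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("effect_size_range must be an ordered pair in [0, 1]")


@dataclass
class GroundTruth:
    """Planted effects underlying a simulated dataset."""

    hits: dict = field(default_factory=dict)                 # (compound, strain) -> effect size
    mics: dict = field(default_factory=dict)                 # (compound, strain) -> MIC or None
    conditional_mutants: dict = field(default_factory=dict)  # mutant -> nrAUC effect
    gene_fitness: dict = field(default_factory=dict)         # gene -> log2 effect
    rule_bits: tuple = ()
    labels: dict = field(default_factory=dict)               # species -> label vector
    community_sensitivity: dict = field(default_factory=dict)


def _plate_layouts(n_compounds: int) -> list[dict[str, WellEntry | None]]:
    """Assign compounds to 96-well plates with controls and the dye well."""
    treatment_wells = [
        f"{r}{c:02d}" for r in _ROWS for c in range(1, 13)
        if f"{r}{c:02d}" not in _CONTROL_WELLS and f"{r}{c:02d}" != _DYE_WELL
    ]
    layouts = []
    i = 0
    while i < n_compounds:
        block = [f"cpd{j:04d}" for j in range(i, min(i + len(treatment_wells), n_compounds))]
        wells: dict[str, WellEntry] = {}
        for w in _CONTROL_WELLS:
            wells[w] = WellEntry("DMSO", 0.0, "vehicle_control")
        wells[_DYE_WELL] = WellEntry("trypan_blue", 0.0, "dye_footprint")
        for w, cpd in zip(treatment_wells, block):
            wells[w] = WellEntry(cpd, 20.0, "treatment")
        for w in treatment_wells[len(block):]:
            wells[w] = WellEntry("", 0.0, "empty")
        layouts.append(wells)
        i += len(treatment_wells)
    return layouts


def gen_screen(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[list[GrowthCurve], dict[str, PlateMap], GroundTruth]:
    """Simulate the monoculture growth screen.

    Logistic growth per well with multiplicative lognormal noise; planted
    compound x strain hits shrink the above-inoculum part of the curve by
    the effect size, so the noiseless normalized AUC equals 1 - effect.
    Optional multiplicative row/column edge effects. Pass a ``truth`` from
    a previous call to re-simulate the same planted effects (independent
    validation experiment).
    """
    rng = _rng(config.seed, "screen")
    layouts = _plate_layouts(config.n_compounds)
    times = np.arange(0.0, config.n_hours + 1.0)
    strains = [f"strain{k:02d}" for k in range(config.n_strains)]
    strain_k = 0.8 + 0.5 * rng.random(config.n_strains)
    strain_r = 0.3 + 0.5 * rng.random(config.n_strains)

    if truth is None:
        truth = GroundTruth()
        n_pairs = int(round(config.hit_fraction * config.n_compounds * config.n_strains))
        all_pairs = [
            (f"cpd{j:04d}", s) for j in range(config.n_compounds) for s in strains
        ]
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        lo, hi = config.effect_size_range
        for k in sorted(idx):
            truth.hits[all_pairs[k]] = float(lo + (hi - lo) * rng.random())
    else:
        rng.random(1)  # keep stream position comparable

    plate_maps: dict[str, PlateMap] = {}
    curves: list[GrowthCurve] = []
    sigma = config.noise_cv
    for p, wells in enumerate(layouts):
        for si, strain in enumerate(strains):
            base = logistic_od(times, strain_k[si], strain_r[si], config.start_od)
            for rep in range(1, config.n_replicates + 1):
                plate_id = f"P{p:02d}_{strain}_r{rep}"
                plate_maps[plate_id] = PlateMap(plate_id, wells)
                well_names = sorted(wells)
                n_w, n_t = len(well_names), times.size
                od = np.tile(base, (n_w, 1))
                for i, w in enumerate(well_names):
                    entry = wells[w]
                    if entry.role in ("dye_footprint", "empty"):
                        od[i] = 0.0 if entry.role == "empty" else 0.9
                        continue
                    effect = truth.hits.get((entry.content_id, strain))
                    if entry.role == "treatment" and effect is not None:
                        od[i] = config.start_od + (1.0 - effect) * (base - config.start_od)
                noise = np.exp(rng.normal(0.0, sigma, size=(n_w, n_t))) if sigma > 0 else 1.0
                od = od * noise
                if config.edge_effect_amplitude > 0:
                    row_f = np.exp(rng.normal(0, config.edge_effect_amplitude, 8))
                    col_f = np.exp(rng.normal(0, config.edge_effect_amplitude, 12))
                    for i, w in enumerate(well_names):
                        od[i] *= row_f[_ROWS.index(w[0])] * col_f[int(w[1:]) - 1]
                for i, w in enumerate(well_names):
                    if wells[w].role == "empty":
                        continue
                    curves.append(GrowthCurve(plate_id, w, strain, rep, times, od[i]))
    return curves, plate_maps, truth


def gen_dose_response(
    config: SimulationConfig,
    planted_mic: dict[tuple[str, str], float | None],
    concentrations=None,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate normalized-AUC dose-response series.

    The response is a Hill curve 1 / (1 + (c / (MIC/2))^4), which in the
    noiseless limit sits below the 0.1 MIC threshold exactly for doses
    >= the planted MIC on two-fold dilution grids. ``planted_mic`` of None
    plants a MIC above the highest tested dose (censored).
    """
    rng = _rng(config.seed, "dose")
    if concentrations is None:
        concentrations = [config.dose_um / 2**k for k in range(7, -1, -1)]
    concentrations = sorted(float(c) for c in concentrations)
    cmax = concentrations[-1]
    truth = GroundTruth(mics=dict(planted_mic))
    rows = []
    for (compound, strain), mic in planted_mic.items():
        mic_eff = mic if mic is not None else 4.0 * cmax
        for c in concentrations:
            response = 1.0 / (1.0 + (c / (mic_eff / 2.0)) ** 4)
            for rep in range(1, n_replicates + 1):
                value = response
                if config.noise_cv > 0:
                    value *= float(np.exp(rng.normal(0.0, config.noise_cv)))
                rows.append(
                    {
                        "compound_id": compound,
                        "strain_id": strain,
                        "concentration": c,
                        "replicate": rep,
                        "norm_auc": value,
                    }
                )
    return pd.DataFrame(rows), truth


def gen_arrayed(
    config: SimulationConfig,
    n_mutants: int = 185,
    n_replicates: int = 2,
    n_technical: int = 2,
    conditional_effects: dict[str, float] | None = None,
    condition: str = "xenobiotic",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an arrayed mutant screen (per-well fitted AUC table).

    ``n_replicates`` independent runs, each inoculated onto ``n_technical``
    technical-replicate plates per condition (the study design). Mutants
    are neutral (AUC drawn around the plate mean with multiplicative
    noise) except those in ``conditional_effects``, whose treatment-arm
    AUC is scaled by the given factor (e.g. 0.5 for a 50% conditional
    growth reduction). Returns the long AUC table consumed by
    :class:`~xenoscreen.arrayed.ArrayedScreen`.
    """
    rng = _rng(config.seed, "arrayed")
    effects = dict(conditional_effects or {})
    mutants = [f"mut{j:03d}" for j in range(n_mutants)]
    per_plate = 80
    rows = []
    for cond_name, is_treatment in ((condition, True), ("DMSO", False)):
        for rep in range(1, n_replicates + 1):
            for tech in range(1, n_technical + 1):
                for p in range(0, n_mutants, per_plate):
                    plate_id = f"A{p // per_plate}"
                    plate_scale = 10.0 * float(np.exp(rng.normal(0, 0.05)))
                    for m in mutants[p: p + per_plate]:
                        auc = plate_scale * float(np.exp(rng.normal(0, config.noise_cv)))
                        if is_treatment and m in effects:
                            auc *= effects[m]
                        rows.append(
                            {
                                "mutant_id": m,
                                "plate_id": plate_id,
                                "condition": cond_name,
                                "replicate": rep,
                                "tech_replicate": tech,
                                "auc": auc,
                            }
                        )
    truth = GroundTruth(conditional_mutants=effects)
    return pd.DataFrame(rows), truth


def gen_tnseq(
    config: SimulationConfig,
) -> tuple[InsertionCountTable, pd.DataFrame, GroundTruth]:
    """Simulate a pooled transposon-fitness competition.

    TA-like insertion sites are placed uniformly within genes (so the
    central-80% mask has tails to remove); site counts are negative
    binomial around lognormal site weights scaled by per-sample sequencing
    depth; planted per-gene fitness scales the condition-arm means by
    2^log2fc.
    """
    tc = config.tnseq
    rng = _rng(config.seed, "tnseq")
    gene_len, spacing = 900, 1000
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{j:04d}" for j in range(tc.n_genes)],
            "start": [1 + j * spacing for j in range(tc.n_genes)],
            "end": [gene_len + j * spacing for j in range(tc.n_genes)],
            "strand": ["+" if j % 2 == 0 else "-" for j in range(tc.n_genes)],
        }
    )
    planted_idx = rng.choice(tc.n_genes, size=tc.n_planted, replace=False)
    gene_fitness = {f"gene{j:04d}": tc.planted_log2fc for j in sorted(planted_idx)}

    positions, gene_ids = [], []
    for j in range(tc.n_genes):
        start = 1 + j * spacing
        offs = np.sort(rng.choice(gene_len, size=tc.sites_per_gene, replace=False))
        for o in offs:
            positions.append(start + int(o))
            gene_ids.append(f"gene{j:04d}")
    sites = pd.DataFrame(
        {
            "position": positions,
            "gene_id": gene_ids,
            "barcode_id": [f"bc{k:06d}" for k in range(len(positions))],
        }
    )
    n_sites = len(sites)
    site_weight = np.exp(rng.normal(0.0, 0.5, size=n_sites))
    site_weight *= tc.mean_count / site_weight.mean()

    sample_ids, conditions, doublings = [], [], []
    for k in range(tc.n_cond):
        sample_ids.append(f"cond_{k + 1}")
        conditions.append("treatment")
        doublings.append(tc.doublings_cond)
    for k in range(tc.n_ctrl):
        sample_ids.append(f"ctrl_{k + 1}")
        conditions.append("control")
        doublings.append(tc.doublings_ctrl)
    samples = pd.DataFrame(
        {"condition": conditions, "replicate": list(range(1, tc.n_cond + 1)) + list(range(1, tc.n_ctrl + 1)),
         "doublings": doublings},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    fitness_scale = np.ones(n_sites)
    for i, gid in enumerate(gene_ids):
        if gid in gene_fitness:
            fitness_scale[i] = 2.0 ** gene_fitness[gid]

    depth = 0.5 + 1.5 * rng.random(len(sample_ids))
    size = 1.0 / tc.dispersion
    counts = np.empty((n_sites, len(sample_ids)), dtype=np.int64)
    for j, cond in enumerate(conditions):
        mean = site_weight * depth[j] * (fitness_scale if cond == "treatment" else 1.0)
        p = size / (size + mean)
        counts[:, j] = rng.negative_binomial(size, p)
    table = InsertionCountTable(
        sites=sites,
        counts=pd.DataFrame(counts, columns=sample_ids),
        samples=samples,
    )
    return table, genes, GroundTruth(gene_fitness=gene_fitness)


def gen_compound_library(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, frozenset], pd.DataFrame, GroundTruth]:
    """Simulate a compound library with a planted structure-activity rule.

    Fingerprint bits are independent Bernoulli draws; a compound is labelled
    active iff every rule bit is set (bit density on the rule bits is
    prevalence^(1/k) so the label prevalence matches the target), with
    optional label-flip noise. The embedding block is a noisy random linear
    projection of the bits, emulating a learned continuous representation.
    """
    mc = config.ml
    rng = _rng(config.seed, "library")
    if not 0 < mc.prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if any(b >= mc.n_features for b in mc.rule_bits):
        raise ValueError("rule_bits must be valid feature indices")
    q = mc.prevalence ** (1.0 / len(mc.rule_bits))
    density = np.full(mc.n_features, mc.background_density)
    density[list(mc.rule_bits)] = q
    bits = (rng.random((mc.n_compounds, mc.n_features)) < density[None, :]).astype(int)
    labels = bits[:, list(mc.rule_bits)].all(axis=1).astype(int)
    if mc.label_noise > 0:
        flip = rng.random(mc.n_compounds) < mc.label_noise
        labels = np.where(flip, 1 - labels, labels)
    W = rng.normal(0.0, 1.0, size=(mc.n_features, mc.embedding_dim))
    emb = bits @ W / np.sqrt(mc.n_features) + 0.1 * rng.normal(
        0.0, 1.0, size=(mc.n_compounds, mc.embedding_dim)
    )
    ids = pd.Index([f"cpd{j:04d}" for j in range(mc.n_compounds)], name="compound_id")
    features = pd.concat(
        [
            pd.DataFrame(bits, index=ids, columns=[f"bit_{k}" for k in range(mc.n_features)]),
            pd.DataFrame(emb, index=ids, columns=[f"emb_{k}" for k in range(mc.embedding_dim)]),
        ],
        axis=1,
    )
    fingerprints = {
        cid: frozenset(np.flatnonzero(bits[i]).tolist()) for i, cid in enumerate(ids)
    }
    label_df = pd.DataFrame({"species_A": labels}, index=ids)
    truth = GroundTruth(rule_bits=tuple(mc.rule_bits), labels={"species_A": labels.copy()})
    return features, fingerprints, label_df, truth


def gen_community(
    config: SimulationConfig,
    sensitivity: dict[str, float] | None = None,
) -> tuple[list[CommunityProfile], GroundTruth]:
    """Simulate treated and control community profiles.

    Control latent abundances come from lognormal species weights summing
    to the control biomass (OD); the treated arm scales each species'
    latent abundance by its planted sensitivity. Read counts are
    multinomial draws at fixed depth and OD is the latent biomass with
    multiplicative noise.
    """
    cc = config.community
    rng = _rng(config.seed, "community")
    species = [f"sp{j:02d}" for j in range(cc.n_species)]
    weights = np.exp(rng.normal(0.0, 1.0, size=cc.n_species))
    base = weights / weights.sum() * cc.od_control
    sens = np.array([(sensitivity or {}).get(s, 1.0) for s in species])

    profiles = []
    for cond, latent in (("control", base), ("treated", base * sens)):
        for rep in range(1, cc.n_replicates + 1):
            props = latent / latent.sum()
            counts = rng.multinomial(cc.depth, props)
            od = float(latent.sum() * np.exp(rng.normal(0.0, cc.noise_cv)))
            profiles.append(
                CommunityProfile(
                    sample_id=f"{cond}_{rep}",
                    counts=dict(zip(species, counts.astype(float))),
                    od=od,
                    condition=cond,
                    replicate=rep,
                )
            )
    truth = GroundTruth(community_sensitivity=dict(zip(species, sens.tolist())))
    return profiles, truth
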