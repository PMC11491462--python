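"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Generates genotypes in Hardy-Weinberg proportions at two named loci
(TRB-like on chromosome 7, HLA-like on chromosome 6), sparse per-variant
effects on latent log RFU abundances, multinomially sampled CDR3
repertoires around centroid templates, logistic-link binary phenotypes
driven by genetically determined RFU components, proportional-hazards
survival times, sorted-subset repertoires with planted enrichment, and a
database of antigen-specific CDR3s.  Every artifact draws from its own
named RNG substream of the master seed, so adding an artifact never
perturbs the others and identical configurations are bit-identical.

The latent abundance model is log-linear with a softmax/multinomial
observation layer: lambda_r = base_r + sum_v dosage_v * effect_vr + noise,
clone counts ~ Multinomial(repertoire_size, softmax(lambda)).  Each clone's
CDR3 string is a point mutation of its RFU's template, verified (and
resampled on failure) to re-assign to the intended centroid.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, softmax

from .encoding import AMINO_ACIDS, AtchleyEncoder
from .phenome import PhenotypeTable
from .qc import GenotypeMatrix
from .quantify import Repertoire, RFUAssigner, RFUCentroids

#: genomic anchors for the two emulated loci (chromosome, first position)
LOCUS_ANCHORS = {"TRB": ("7", 142_000_000), "HLA": ("6", 29_600_000)}
VARIANT_SPACING = 2_000  # bp between successive synthetic variants


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults emulate a realistic cohort.

    ``repertoire_size_range`` is in unique clonotypes per individual,
    bracketing the observed per-individual unique-CDR3 scale;
    ``disease_effect`` is the log-odds increment per SD of the driving
    gdRFU and ``hazard_ratio`` the multiplicative hazard per SD.
    """

    n_individuals: int = 500
    n_variants_per_locus: dict = field(default_factory=lambda: {"TRB": 120, "HLA": 80})
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_rfus: int = 50
    n_causal_variants_per_rfu: int = 3
    effect_size_sd: float = 0.5
    latent_noise_sd: float = 0.1
    repertoire_size_range: tuple[int, int] = (5_000, 20_000)
    disease_effect: float = 0.3
    baseline_prevalence: float = 0.05
    hazard_ratio: float = 1.5
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_rfus < 1:
            raise ValueError("counts must be positive")
        if any(n < 1 for n in self.n_variants_per_locus.values()):
            raise ValueError("variant counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        rlo, rhi = self.repertoire_size_range
        if rlo < 1 or rhi < rlo:
            raise ValueError("invalid repertoire_size_range")
        if self.n_causal_variants_per_rfu < 0:
            raise ValueError("n_causal_variants_per_rfu must be >= 0")

    @property
    def n_variants(self) -> int:
        return sum(self.n_variants_per_locus.values())

    def rng(self, stream: str) -> np.random.Generator:
        """Named RNG substream derived from the master seed."""
        return np.random.default_rng(
            [int(self.seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())]
        )


@dataclass
class EffectMap:
    """Sparse ground-truth variant effects on latent RFU log-abundance."""

    effects: pd.DataFrame  # variants x RFUs
    causal: dict           # rfu_id -> list of causal variant ids


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Dosages in {0,1,2} per variant as Binomial(2, p), p ~ U(maf_range)."""
    rng = config.rng("genotypes")
    cols = {}
    meta = []
    for locus, n_var in config.n_variants_per_locus.items():
        chrom, start = LOCUS_ANCHORS.get(locus, (locus, 1_000_000))
        freqs = rng.uniform(*config.maf_range, size=n_var)
        for k in range(n_var):
            vid = f"{locus}_v{k}"
            cols[vid] = rng.binomial(2, freqs[k], size=config.n_individuals)
            meta.append((vid, chrom, start + k * VARIANT_SPACING, locus, "A", "G"))
    individuals = [f"I{i:05d}" for i in range(config.n_individuals)]
    dosages = pd.DataFrame(cols, index=individuals)
    variants = pd.DataFrame(
        meta, columns=["id", "chrom", "pos", "locus", "ref", "alt"]
    ).set_index("id")
    return GenotypeMatrix(dosages, variants)


def simulate_rfu_effects(config: SimulationConfig, genotypes: GenotypeMatrix | None = None) -> EffectMap:
    """Exactly ``n_causal_variants_per_rfu`` Normal(0, sd^2) effects per RFU."""
    if config.n_causal_variants_per_rfu > config.n_variants:
        raise ValueError("n_causal_variants_per_rfu exceeds the variant count")
    rng = config.rng("effects")
    if genotypes is not None:
        variant_ids = genotypes.variant_ids
    else:
        variant_ids = [
            f"{locus}_v{k}"
            for locus, n in config.n_variants_per_locus.items()
            for k in range(n)
        ]
    rfu_ids = [f"RFU{r}" for r in range(config.n_rfus)]
    eff = np.zeros((len(variant_ids), config.n_rfus))
    causal: dict = {}
    for r in range(config.n_rfus):
        idx = rng.choice(len(variant_ids), size=config.n_causal_variants_per_rfu, replace=False)
        eff[idx, r] = rng.normal(0.0, config.effect_size_sd, size=idx.size)
        causal[rfu_ids[r]] = [variant_ids[i] for i in sorted(idx)]
    return EffectMap(
        effects=pd.DataFrame(eff, index=variant_ids, columns=rfu_ids),
        causal=causal,
    )


def simulate_centroids(
    config: SimulationConfig,
    encoder: AtchleyEncoder | None = None,
    length_range: tuple[int, int] = (10, 18),
) -> tuple[RFUCentroids, list[str]]:
    """One template CDR3 per RFU; centroid = the template's embedding."""
    rng = config.rng("centroids")
    encoder = encoder or AtchleyEncoder()
    templates: list[str] = []
    seen = set()
    while len(templates) < config.n_rfus:
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        middle = "".join(rng.choice(list(AMINO_ACIDS), size=L - 2))
        t = "C" + middle + "F"
        if t not in seen:
            seen.add(t)
            templates.append(t)
    matrix = encoder.encode_many(templates)
    rfu_ids = [f"RFU{r}" for r in range(config.n_rfus)]
    return RFUCentroids(matrix=matrix, rfu_ids=rfu_ids), templates


def _mutant_batch(
    template: str, n: int, rng: np.random.Generator, max_mut: int = 2
) -> list[str]:
    """n substitution mutants of a template (1..max_mut interior residues)."""
    L = len(template)
    base = np.array(list(template))
    out = []
    n_mut = rng.integers(1, max_mut + 1, size=n)
    for i in range(n):
        arr = base.copy()
        pos = rng.choice(np.arange(1, L - 1), size=min(int(n_mut[i]), L - 2), replace=False)
        for p in pos:
            arr[p] = AMINO_ACIDS[int(rng.integers(0, 20))]
        out.append("".join(arr))
    return out


def _clones_for_rfu(
    template: str,
    target_idx: int,
    n: int,
    rng: np.random.Generator,
    assigner: RFUAssigner,
    max_rounds: int = 20,
) -> list[str]:
    """Generate n distinct CDR3 strings verified to re-assign to the target.

    Mutants failing nearest-centroid verification, or duplicating an
    already-accepted clone, are resampled; later rounds allow more
    substitutions so the mutant space cannot be exhausted.  A stubborn
    remainder falls back to the unmutated template (which maps to its own
    centroid by construction) and, past that, to duplicates.
    """
    accepted: list[str] = []
    seen: set[str] = set()
    need = n
    for round_no in range(max_rounds):
        if need == 0:
            break
        max_mut = 2 if round_no < 3 else min(2 + round_no - 2, max(len(template) - 2, 1))
        cand = _mutant_batch(template, need + need // 4 + 1, rng, max_mut=max_mut)
        fresh = [s for s in dict.fromkeys(cand) if s not in seen]
        if not fresh:
            continue
        idx = assigner.assign_indices(fresh)
        for s, j in zip(fresh, idx):
            if j == target_idx and need > 0:
                accepted.append(s)
                seen.add(s)
                need -= 1
    if need > 0 and template not in seen:
        accepted.append(template)
        need -= 1
    accepted.extend([template] * need)
    return accepted


def latent_genetic_values(genotypes: GenotypeMatrix, effects: EffectMap) -> pd.DataFrame:
    """Genetic component of latent log-abundance, individuals x RFUs."""
    X = genotypes.dosages.to_numpy(dtype=float)
    B = effects.effects.loc[genotypes.variant_ids].to_numpy()
    return pd.DataFrame(
        X @ B, index=genotypes.individual_ids, columns=effects.effects.columns
    )


def simulate_repertoires(
    genotypes: GenotypeMatrix,
    effects: EffectMap,
    centroids: RFUCentroids,
    config: SimulationConfig,
    templates: list[str],
    encoder: AtchleyEncoder | None = None,
) -> list[Repertoire]:
    """Per-individual clone sets: multinomial counts around softmax(lambda).

    Each multinomial draw of RFU r becomes one unique clonotype generated
    from r's template (clone counts 1 + Poisson(0.5)); the generator
    verifies nearest-centroid recovery of every clone and resamples
    failures, so encode -> assign recovers the intended RFU for >= 95% of
    clones.
    """
    if list(effects.effects.columns) != list(centroids.rfu_ids):
        raise ValueError("effect map and centroid RFU ids disagree")
    if len(templates) != centroids.n_rfus:
        raise ValueError("one template per centroid required")
    rng = config.rng("repertoires")
    assigner = RFUAssigner(encoder=encoder).fit(centroids)
    base = config.rng("base_abundance").normal(0.0, 1.0, size=config.n_rfus)
    gvals = latent_genetic_values(genotypes, effects).to_numpy()
    lo, hi = config.repertoire_size_range
    repertoires = []
    for i, ind in enumerate(genotypes.individual_ids):
        lam = base + gvals[i]
        if config.latent_noise_sd > 0:
            lam = lam + rng.normal(0.0, config.latent_noise_sd, size=config.n_rfus)
        size = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(size, softmax(lam))
        clones: dict[str, int] = {}
        for r in np.flatnonzero(counts):
            for seq in _clones_for_rfu(templates[r], int(r), int(counts[r]), rng, assigner):
                clones[seq] = clones.get(seq, 0) + 1 + int(rng.poisson(0.5))
        repertoires.append(Repertoire(individual_id=ind, clones=clones))
    return repertoires


def simulate_covariates(config: SimulationConfig, individual_ids=None) -> pd.DataFrame:
    """sex ~ Bernoulli(0.5), age ~ U(40, 70), five synthetic PCs ~ N(0, 1)."""
    rng = config.rng("covariates")
    n = config.n_individuals if individual_ids is None else len(individual_ids)
    ids = individual_ids if individual_ids is not None else [f"I{i:05d}" for i in range(n)]
    data = {
        "sex": rng.integers(0, 2, size=n).astype(float),
        "age": rng.uniform(40.0, 70.0, size=n),
    }
    for k in range(5):
        data[f"PC{k + 1}"] = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(data, index=ids)


def simulate_phenotypes(
    genetic_values: pd.DataFrame,
    config: SimulationConfig,
    driver_rfus: tuple = None,
    n_null_traits: int = 0,
    sex_effect: float = 0.2,
    age_effect: float = 0.01,
) -> PhenotypeTable:
    """Binary and survival phenotypes driven by designated gdRFU components.

    Disease: Bernoulli(logistic(logit(prevalence) + disease_effect * z +
    covariate terms)) where z is the standardized genetic value of the
    driver RFU.  Survival: Exponential with hazard
    h0 * hazard_ratio^z, with independent Exponential censoring tuned to
    the configured censoring rate.  One binary trait and one survival
    endpoint per driver, plus ``n_null_traits`` pure-noise diseases.
    """
    if driver_rfus is None:
        driver_rfus = (genetic_values.columns[0],)
    if len(driver_rfus) == 0:
        raise ValueError("at least one driver RFU required")
    rng = config.rng("phenotypes")
    ids = genetic_values.index
    n = len(ids)
    covariates = simulate_covariates(config, individual_ids=list(ids))
    cov_term = sex_effect * (covariates["sex"] - 0.5) + age_effect * (covariates["age"] - 55.0)

    binary = {}
    survival = {}
    base_logit = logit(config.baseline_prevalence)
    log_hr = np.log(config.hazard_ratio)
    for rfu in driver_rfus:
        g = genetic_values[rfu].to_numpy(dtype=float)
        sd = g.std(ddof=0)
        z = (g - g.mean()) / sd if sd > 0 else np.zeros(n)
        prob = expit(base_logit + config.disease_effect * z + cov_term.to_numpy())
        binary[f"disease_{rfu}"] = rng.binomial(1, prob)
        hazard = config.baseline_hazard * np.exp(log_hr * z)
        t_event = rng.exponential(1.0 / hazard)
        if config.censoring_rate > 0:
            hc = config.baseline_hazard * config.censoring_rate / (1.0 - config.censoring_rate)
            t_cens = rng.exponential(1.0 / hc, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        survival[f"survival_{rfu}"] = pd.DataFrame(
            {
                "time": time,
                "event": event,
                "diagnosis_age": covariates["age"].to_numpy(),
            },
            index=ids,
        )
    for k in range(n_null_traits):
        prob = expit(base_logit + cov_term.to_numpy())
        binary[f"null_{k}"] = rng.binomial(1, prob)

    return PhenotypeTable(
        binary=pd.DataFrame(binary, index=ids),
        survival=survival,
        covariates=covariates,
    )


def simulate_sorted_subsets(
    centroids: RFUCentroids,
    templates: list[str],
    subset_profiles: dict,
    config: SimulationConfig,
    n_individuals: int = 15,
    repertoire_size: int = 2_000,
    encoder: AtchleyEncoder | None = None,
) -> tuple[dict, dict]:
    """Sorted-compartment repertoires with subset-specific RFU propensities.

    ``subset_profiles`` maps subset name -> length-n_rfus multiplicative
    propensity vector (1.0 = baseline); clone sampling follows
    softmax(base + log propensity) per subset.  Returns
    (subset -> list of Repertoire, ground-truth rfu_id -> enriched subset
    for RFUs whose propensity is maximal in a unique subset above 1).
    """
    if not subset_profiles:
        raise ValueError("empty subset profile")
    for name, prof in subset_profiles.items():
        if len(np.asarray(prof)) != centroids.n_rfus:
            raise ValueError(f"profile for {name!r} has wrong length")
    rng = config.rng("sorted_subsets")
    assigner = RFUAssigner(encoder=encoder).fit(centroids)
    base = config.rng("base_abundance").normal(0.0, 1.0, size=centroids.n_rfus)
    out: dict = {}
    for subset in subset_profiles:
        prof = np.asarray(subset_profiles[subset], dtype=float)
        probs = softmax(base + np.log(prof))
        reps = []
        for i in range(n_individuals):
            counts = rng.multinomial(repertoire_size, probs)
            clones: dict[str, int] = {}
            for r in np.flatnonzero(counts):
                for seq in _clones_for_rfu(templates[r], int(r), int(counts[r]), rng, assigner):
                    clones[seq] = clones.get(seq, 0) + 1
            reps.append(Repertoire(individual_id=f"{subset}_I{i:03d}", clones=clones))
        out[subset] = reps
    truth = {}
    prof_matrix = np.array([np.asarray(subset_profiles[s], float) for s in subset_profiles])
    names = list(subset_profiles)
    for r in range(centroids.n_rfus):
        col = prof_matrix[:, r]
        top = col.max()
        if top > 1.0 and (col == top).sum() == 1:
            truth[centroids.rfu_ids[r]] = names[int(col.argmax())]
    return out, truth


def simulate_antigen_db(
    centroids: RFUCentroids,
    templates: list[str],
    specific_rfus,
    config: SimulationConfig,
    n_sequences_per_rfu: int = 10,
    antigens: dict | None = None,
    encoder: AtchleyEncoder | None = None,
):
    """Antigen-specific CDR3 table whose sequences map into designated RFUs.

    ``specific_rfus`` is a set of RFU ids; ``antigens`` optionally maps an
    RFU id to a list of antigen labels (default a single synthetic label
    per RFU).  Sequences are verified mutants of the RFU template, so
    re-assignment recovers the intended RFU.
    """
    from .annotation import AntigenTCRTable

    rfu_index = {r: i for i, r in enumerate(centroids.rfu_ids)}
    unknown = set(specific_rfus) - set(rfu_index)
    if unknown:
        raise ValueError(f"unknown RFU ids: {sorted(unknown)}")
    rng = config.rng("antigen_db")
    assigner = RFUAssigner(encoder=encoder).fit(centroids)
    rows = []
    for rfu in sorted(specific_rfus, key=str):
        labels = (antigens or {}).get(rfu, [f"antigen_{rfu}"])
        seqs = _clones_for_rfu(
            templates[rfu_index[rfu]], rfu_index[rfu], n_sequences_per_rfu, rng, assigner
        )
        for i, seq in enumerate(seqs):
            rows.append((seq, labels[i % len(labels)], "synthetic"))
    return AntigenTCRTable(
        table=pd.DataFrame(rows, columns=["cdr3_aa", "antigen", "source"])
    )
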