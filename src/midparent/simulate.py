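"""Synthetic hybrid-panel generator with full ground truth.

The generator emulates a multiplexed quantitative proteomics study of a hybrid
panel: two-parent crosses with dominance architecture, trait-coupled expression
heterosis, log-normal replicate noise, multiplicative run (plex) effects with
the anchor genotype present in every run, an ethylene-mutant phenocopy
experiment, and locus-level RIL backcross heterozygosity.

Generative model (all draws from seeded generators, bit-reproducible):

* feature baseline log2 level  mu_i ~ Normal(10, 1)
* parent p level               2**(mu_i + a_ip),  a_ip ~ Normal(0, sigma_g)
* hybrid j true level          MP_ij * f_ij,
  f_ij = max(1 + delta_i + beta_i * (h_j - 1) + eps_ij, f_floor),
  eps_ij ~ Normal(0, sigma_c)
* replicate observation        true * 2**Normal(0, sigma_r) * run_effect(run)
* run effect                   2**Normal(0, sigma_b) per run
* inbred heights ~ Normal(150, 10); hybrid height = MP_height * h_j,
  h_j ~ Uniform(1.2, 1.8)

delta_i is the dominance deviation on the ratio scale (0 for additive
features), beta_i the trait-coupling slope (nonzero only for the designated
coupled group, which stands in for the plastid-ribosome biomarkers).
Structure (genetics, heights), noise (replicates, coupling) and run effects
are drawn from three separate seed streams so that run effects can be switched
off without disturbing any other draw.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix, AnnotationTable, CrossPanel, SampleDesign, TraitTable

DOMINANCE_MODES = ("additive", "dominant", "overdominant", "underdominant")

#: Group labels handed to non-coupled features, weighted toward "other" so the
#: annotation resembles a sparse functional catalog.
_BACKGROUND_GROUPS = ("PhANG", "PhAPG", "cytosolic_ribosome", "TPR", "carbon_fixation", "other")
_BACKGROUND_PROBS = (0.03, 0.01, 0.05, 0.01, 0.02, 0.88)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for the panel generator.

    Defaults mirror the emulated study: a 15-hybrid panel (all pairwise
    crosses of six inbreds), four biological replicates per genotype laid out
    as one replicate per run with the anchor inbred in every run, log2
    replicate noise 0.15, run effects 0.3, parental genetic effects 0.5, and a
    100-feature trait-coupled group with slope 1 and coupling noise 0.05.
    """

    n_features: int = 2000
    parents: tuple[str, ...] = ("P01", "P02", "P03", "P04", "P05", "P06")
    crosses: tuple[tuple[str, str], ...] | None = None  # default: all pairs
    replicates: int = 4
    anchor: str | None = None  # default: first parent
    sigma_r: float = 0.15  # replicate noise, log2 scale
    sigma_b: float = 0.3  # run effect, log2 scale
    sigma_g: float = 0.5  # parental genetic effect, log2 scale
    sigma_c: float = 0.05  # coupling noise on the heterosis factor (ratio scale)
    fraction_additive: float = 0.7
    fraction_dominant: float = 0.15
    fraction_overdominant: float = 0.075
    fraction_underdominant: float = 0.075
    coupled_size: int = 100
    coupling_beta: float = 1.0
    height_mean: float = 150.0
    height_sd: float = 10.0
    h_range: tuple[float, float] = (1.2, 1.8)
    f_floor: float = 0.05
    anchor_reps_per_run: int = 4  # reference-channel replicates of the anchor in each run
    tissue: str = "seedling_leaf"
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (
            self.fraction_additive,
            self.fraction_dominant,
            self.fraction_overdominant,
            self.fraction_underdominant,
        )
        if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("dominance fractions must be nonnegative and sum to 1")
        for name in ("sigma_r", "sigma_b", "sigma_g", "sigma_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.h_range
        if not (0 < lo <= hi):
            raise ValueError("h_range must be positive and ordered")
        if self.replicates < 1 or self.n_features < 1:
            raise ValueError("replicates and n_features must be positive")
        if len(self.parents) < 2:
            raise ValueError("at least two parents required")
        if self.coupled_size > int(round(self.fraction_additive * self.n_features)):
            raise ValueError("coupled_size exceeds the additive feature pool")
        if self.anchor_reps_per_run < 1:
            raise ValueError("anchor_reps_per_run must be >= 1")

    @property
    def anchor_genotype(self) -> str:
        return self.anchor if self.anchor is not None else self.parents[0]

    @property
    def cross_list(self) -> tuple[tuple[str, str], ...]:
        if self.crosses is not None:
            return self.crosses
        pairs = []
        for i, a in enumerate(self.parents):
            for b in self.parents[i + 1:]:
                pairs.append((a, b))
        return tuple(pairs)


def additive_null_config(**overrides) -> SimConfig:
    """A pure-additivity configuration: no dominance, no coupling, no coupling noise."""
    base = dict(
        fraction_additive=1.0,
        fraction_dominant=0.0,
        fraction_overdominant=0.0,
        fraction_underdominant=0.0,
        coupled_size=0,
        sigma_c=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to reproduce the emitted matrix exactly."""

    config: SimConfig
    features: pd.DataFrame  # feature_id, mode, delta, beta, group
    hybrids: pd.DataFrame  # hybrid, parent_female, parent_male, h
    run_effects: pd.Series  # run -> multiplicative effect
    levels: pd.DataFrame  # true level per feature x genotype
    f_factors: pd.DataFrame  # realized heterosis factor per feature x hybrid
    noise_factors: pd.DataFrame  # replicate noise multiplier per feature x sample

    def reconstruct_value(self, feature_id: str, sample_id: str, design: SampleDesign) -> float:
        row = design.table[design.table["sample_id"] == sample_id].iloc[0]
        return (
            self.levels.loc[feature_id, row["genotype"]]
            * self.noise_factors.loc[feature_id, sample_id]
            * self.run_effects[row["run"]]
        )


class PanelSim(NamedTuple):
    matrix: AbundanceMatrix
    design: SampleDesign
    panel: CrossPanel
    traits: TraitTable
    annotation: AnnotationTable
    truth: SyntheticTruth


def _assign_modes(config: SimConfig, rng: np.random.Generator):
    """Dominance mode, delta and beta per feature (largest-remainder counts)."""
    n = config.n_features
    fractions = np.array(
        [
            config.fraction_additive,
            config.fraction_dominant,
            config.fraction_overdominant,
            config.fraction_underdominant,
        ]
    )
    counts = np.floor(fractions * n).astype(int)
    remainder = fractions * n - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    modes = np.repeat(np.array(DOMINANCE_MODES, dtype=object), counts)
    modes = modes[rng.permutation(n)]

    delta = np.zeros(n)
    dom = modes == "dominant"
    delta[dom] = rng.uniform(0.1, 0.4, dom.sum()) * rng.choice([-1.0, 1.0], dom.sum())
    over = modes == "overdominant"
    delta[over] = rng.uniform(0.3, 0.8, over.sum())
    under = modes == "underdominant"
    delta[under] = -rng.uniform(0.3, 0.8, under.sum())

    beta = np.zeros(n)
    additive_idx = np.flatnonzero(modes == "additive")
    coupled_idx = rng.choice(additive_idx, size=config.coupled_size, replace=False)
    beta[coupled_idx] = config.coupling_beta

    groups = rng.choice(_BACKGROUND_GROUPS, size=n, p=_BACKGROUND_PROBS).astype(object)
    # coupled features stand in for the plastid ribosome, half nuclear- and
    # half plastid-encoded
    half = len(coupled_idx) // 2
    groups[np.sort(coupled_idx)[:half]] = "plastid_ribosome_NE"
    groups[np.sort(coupled_idx)[half:]] = "plastid_ribosome_PE"
    return modes, delta, beta, groups, np.sort(coupled_idx)


def simulate_panel(config: SimConfig) -> PanelSim:
    """Generate a full panel: abundance matrix, metadata tables and ground truth."""
    ss_structure, ss_noise, ss_run = np.random.SeedSequence(config.seed).spawn(3)
    rng_s = np.random.default_rng(ss_structure)
    rng_n = np.random.default_rng(ss_noise)
    rng_r = np.random.default_rng(ss_run)

    n = config.n_features
    parents = list(config.parents)
    crosses = config.cross_list
    hybrids = [f"{a}x{b}" for a, b in crosses]
    feature_ids = [f"F{i:05d}" for i in range(1, n + 1)]

    # --- structure stream ---------------------------------------------------
    mu = rng_s.normal(10.0, 1.0, n)
    a = rng_s.normal(0.0, config.sigma_g, (n, len(parents)))
    modes, delta, beta, groups, _ = _assign_modes(config, rng_s)
    inbred_heights = rng_s.normal(config.height_mean, config.height_sd, len(parents))
    inbred_heights = np.maximum(inbred_heights, 1.0)
    h = rng_s.uniform(config.h_range[0], config.h_range[1], len(hybrids))

    parent_levels = 2.0 ** (mu[:, None] + a)  # features x parents

    # --- noise stream: coupling noise then replicate noise -------------------
    eps = rng_n.normal(0.0, 1.0, (n, len(hybrids))) * config.sigma_c
    f = 1.0 + delta[:, None] + beta[:, None] * (h[None, :] - 1.0) + eps
    f = np.maximum(f, config.f_floor)

    parent_idx = {p: i for i, p in enumerate(parents)}
    hybrid_levels = np.empty((n, len(hybrids)))
    for j, (pf, pm) in enumerate(crosses):
        mp = (parent_levels[:, parent_idx[pf]] + parent_levels[:, parent_idx[pm]]) / 2.0
        hybrid_levels[:, j] = mp * f[:, j]

    genotypes = parents + hybrids
    levels = np.concatenate([parent_levels, hybrid_levels], axis=1)

    # design: replicate k of every genotype lives in run k (a complete block),
    # and the anchor inbred contributes `anchor_reps_per_run` reference
    # replicates to every run, numbered so its first `replicates` replicates
    # span the runs one-per-run like every other genotype
    anchor = config.anchor_genotype
    R = config.replicates
    rows = []
    for g in genotypes:
        role = "inbred" if g in parent_idx else "hybrid"
        n_per_run = config.anchor_reps_per_run if g == anchor else 1
        for j in range(n_per_run):
            for k in range(1, R + 1):
                rep = j * R + k
                rows.append(
                    {
                        "sample_id": f"{g}.r{rep}",
                        "genotype": g,
                        "replicate": rep,
                        "run": f"run{k}",
                        "tissue": config.tissue,
                        "role": role,
                    }
                )
    design = SampleDesign(pd.DataFrame(rows))
    sample_ids = design.sample_ids
    runs = design.runs

    noise = 2.0 ** rng_n.normal(0.0, config.sigma_r, (n, len(sample_ids)))
    run_effects = pd.Series(
        2.0 ** (rng_r.normal(0.0, 1.0, len(runs)) * config.sigma_b), index=runs
    )

    geno_col = design.table["genotype"].to_numpy()
    run_col = design.table["run"].to_numpy()
    geno_pos = {g: i for i, g in enumerate(genotypes)}
    values = (
        levels[:, [geno_pos[g] for g in geno_col]]
        * noise
        * run_effects[run_col].to_numpy()[None, :]
    )

    matrix = AbundanceMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids))
    panel = CrossPanel(
        pd.DataFrame(
            {"hybrid": hybrids, "parent_female": [c[0] for c in crosses],
             "parent_male": [c[1] for c in crosses]}
        )
    )
    mp_heights = np.array(
        [
            (inbred_heights[parent_idx[pf]] + inbred_heights[parent_idx[pm]]) / 2.0
            for pf, pm in crosses
        ]
    )
    traits = TraitTable(
        pd.DataFrame(
            {
                "genotype": genotypes,
                "height_cm": np.concatenate([inbred_heights, mp_heights * h]),
            }
        )
    )
    annotation = AnnotationTable(
        pd.DataFrame({"feature_id": feature_ids, "groups": [frozenset({g}) for g in groups]})
    )
    truth = SyntheticTruth(
        config=config,
        features=pd.DataFrame(
            {"feature_id": feature_ids, "mode": modes, "delta": delta,
             "beta": beta, "group": groups}
        ).set_index("feature_id"),
        hybrids=pd.DataFrame(
            {"hybrid": hybrids, "parent_female": [c[0] for c in crosses],
             "parent_male": [c[1] for c in crosses], "h": h}
        ).set_index("hybrid"),
        run_effects=run_effects,
        levels=pd.DataFrame(levels, index=feature_ids, columns=genotypes),
        f_factors=pd.DataFrame(f, index=feature_ids, columns=hybrids),
        noise_factors=pd.DataFrame(noise, index=feature_ids, columns=sample_ids),
    )
    return PanelSim(matrix, design, panel, traits, annotation, truth)


class MutantSim(NamedTuple):
    matrix: AbundanceMatrix
    design: SampleDesign
    truth: pd.DataFrame  # feature_id -> nonadditive, concordant, true_ratio


def simulate_mutant(
    config: SimConfig,
    truth: SyntheticTruth,
    concordance: float = 1.0,
    seed: int = 0,
    reference_hybrid: str | None = None,
    mutant_name: str = "mut_et",
    n_replicates: int | None = None,
) -> MutantSim:
    """Simulate a mutant that phenocopies a reference hybrid with probability pi.

    For each feature nonadditive in the reference hybrid (dominance deviation
    or trait coupling, so its realized heterosis factor f != 1), the
    mutant/background true ratio equals f with probability ``concordance`` and
    1/f otherwise; additive features are unchanged.  Fresh background
    (= anchor inbred) and mutant replicates are drawn with the panel's
    replicate noise, one replicate per new run.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    if reference_hybrid is None:
        reference_hybrid = truth.hybrids["h"].idxmax()
    if reference_hybrid not in truth.f_factors.columns:
        raise ValueError(f"reference hybrid '{reference_hybrid}' absent from truth")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    background = config.anchor_genotype
    features = truth.features.index
    f_ref = truth.f_factors[reference_hybrid].to_numpy()
    nonadditive = (truth.features["mode"] != "additive").to_numpy() | (
        truth.features["beta"] != 0
    ).to_numpy()

    match = rng.random(len(features)) < concordance
    ratio = np.ones(len(features))
    ratio[nonadditive & match] = f_ref[nonadditive & match]
    ratio[nonadditive & ~match] = 1.0 / f_ref[nonadditive & ~match]

    bg_level = truth.levels[background].to_numpy()
    mut_level = bg_level * ratio

    reps = n_replicates or config.replicates
    rows = []
    cols = []
    level_cols = []
    for k in range(1, reps + 1):
        run = f"mutant_run{k}"
        for g, level, role in (
            (background, bg_level, "inbred"),
            (mutant_name, mut_level, "mutant"),
        ):
            sid = f"{g}.m.r{k}"
            rows.append(
                {"sample_id": sid, "genotype": g, "replicate": k, "run": run,
                 "tissue": config.tissue, "role": role}
            )
            cols.append(sid)
            level_cols.append(level)
    noise = 2.0 ** rng.normal(0.0, config.sigma_r, (len(features), len(cols)))
    values = np.column_stack(level_cols) * noise
    matrix = AbundanceMatrix(pd.DataFrame(values, index=features, columns=cols))
    design = SampleDesign(pd.DataFrame(rows))
    mut_truth = pd.DataFrame(
        {
            "nonadditive": nonadditive,
            "concordant": np.where(nonadditive, match, np.nan),
            "true_ratio": ratio,
            "reference_hybrid": reference_hybrid,
        },
        index=features,
    )
    return MutantSim(matrix, design, mut_truth)


def backcross_heterozygosity(alleles: np.ndarray) -> np.ndarray:
    """Per-RIL heterozygous fraction of the backcross to the recurrent founder.

    ``alleles`` is a RIL x locus matrix of 0/1 founder-of-origin codes, with 0
    the recurrent founder.  The backcross is heterozygous exactly at loci where
    the (fully inbred) RIL carries the other founder's allele; the F1 is
    heterozygous at every locus, so the fraction is already relative to the F1.
    """
    alleles = np.asarray(alleles)
    return alleles.mean(axis=1)


def simulate_ril_heterozygosity(
    n_loci: int, n_rils: int, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Heterozygosity of RIL-to-founder backcross hybrids relative to the F1.

    Each fully inbred RIL draws every locus independently from either founder
    with equal probability.  Returns (per-RIL fractions, panel mean); the
    expectation of the mean is 1/2, i.e. backcross hybrids are half as
    heterozygous as the F1.
    """
    if n_loci < 1 or n_rils < 1:
        raise ValueError("n_loci and n_rils must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alleles = rng.integers(0, 2, size=(n_rils, n_loci))
    fractions = backcross_heterozygosity(alleles)
    return fractions, float(fractions.mean())


def with_sigma_b(config: SimConfig, sigma_b: float) -> SimConfig:
    """Same configuration with a different run-effect magnitude (shared streams)."""
    return replace(config, sigma_b=sigma_b)
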