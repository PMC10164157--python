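"""Synthetic dual-cassette dropout screens with known ground truth.

The generator emulates the screening setup this package analyses: a 160 x 160
combination library (10 CE + 10 TS genes x 4 guides + 80 NHT controls per
cassette), lentiviral-representation skew, ~10 population doublings at 100x
coverage in duplicate, per-guide activity variation, and per-design RNA
processing penalties that render hybrid-transcript (CHyMErA-type) guides
partially inactive.

Model: gene fitness f is the log2 abundance change per doubling conferred by
a fully active guide (CE genes f < 0, TS genes f > 0, NHT f = 0).  Guide
activity a is in [0, 1]; design position penalties pi scale each cassette's
contribution.  The expected combination LFC after d doublings is, under the
additive rule,

    mu = d * (f_A * a_1 * pi_1 + f_B * a_2 * pi_2)

Counts are multinomial draws at the configured depth, from initial abundances
with lognormal representation skew for the reference sample and from
abundances reweighted by 2^mu for end replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import (
    SPACER_LEN,
    CombinatorialLibrary,
    GuideRecord,
    LibraryDesign,
    build_library,
    get_design,
)
from .quantify import CountTable

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated screen (defaults = the emulated study design)."""

    design: str = "SpCas9"
    n_ce: int = 10
    n_ts: int = 10
    guides_per_gene: int = 4
    n_nht: int = 80
    doublings: float = 10.0
    coverage: int = 100
    replicates: int = 2
    #: per-class gene fitness (mean, sd), log2 per doubling at full activity
    f_ce: tuple[float, float] = (-0.43, 0.08)
    f_ts: tuple[float, float] = (0.23, 0.05)
    #: genes per class with a strong (gold-positive) effect; the remaining
    #: library genes get fitness scaled by f_weak_scale and form the ROC
    #: negative class, mirroring benchmark gene sets with 6 CE + 5 TS
    #: conserved strong dependencies and 9 non-essential negatives
    n_ce_gold: int = 6
    n_ts_gold: int = 5
    f_weak_scale: float = 0.25
    #: guide activity ~ lo + (hi-lo) * Beta(alpha, beta)
    activity_beta: tuple[float, float] = (6.0, 2.0)
    activity_range: tuple[float, float] = (0.0, 1.0)
    #: lognormal sigma of initial library representation; 0.3 gives a P90/P10
    #: skew of ~2.2, i.e. a library passing the < 2.5 uniformity criterion
    initial_sigma: float = 0.3
    #: reads per sample; None = coverage * n_combinations
    depth: int | None = None
    combination_rule: str = "additive"
    #: interaction (epistasis) coefficient added to mu for double-target pairs
    interaction: float = 0.0
    #: Dirichlet-multinomial concentration; None = plain multinomial
    overdispersion: float | None = None
    #: fraction of AsCas12a guides carrying a canonical TTTV PAM
    tttv_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.combination_rule not in ("additive", "max"):
            raise ValueError("combination_rule must be 'additive' or 'max'")
        lo, hi = self.activity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("activity_range must satisfy 0 <= lo <= hi <= 1")
        if min(self.doublings, self.coverage) <= 0:
            raise ValueError("doublings and coverage must be positive")
        if self.activity_beta[0] <= 0 or self.activity_beta[1] <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def n_per_position(self) -> int:
        return (self.n_ce + self.n_ts) * self.guides_per_gene + self.n_nht

    def effective_depth(self, n_combinations: int) -> int:
        return self.depth if self.depth is not None else self.coverage * n_combinations

    @classmethod
    def strong_effects(cls, design: str = "SpCas9", **kw) -> "SimulationConfig":
        """Strong, uniformly active perturbations: |f_CE| * d >= 4, a >= 0.8."""
        return cls(
            design=design,
            f_ce=(-0.45, 0.03),
            f_ts=(0.25, 0.03),
            activity_beta=(2.0, 2.0),
            activity_range=(0.8, 1.0),
            **kw,
        )

    @classmethod
    def null(cls, design: str = "SpCas9", **kw) -> "SimulationConfig":
        """No fitness effects anywhere (label-free null screen)."""
        return cls(design=design, f_ce=(0.0, 0.0), f_ts=(0.0, 0.0), **kw)


@dataclass
class TrueEffects:
    """Ground truth of a simulated screen.

    ``frame`` holds, per combination, the pre-penalty position contributions
    contrib_i = f_gene * a_eff (so mu = d * (contrib1*pi1 + contrib2*pi2)
    + interaction), the realized mu, and gene annotation.
    """

    gene_fitness: pd.Series
    guide_activity: pd.Series
    frame: pd.DataFrame  # index combo_id; columns contrib1, contrib2, interaction, mu
    doublings: float
    penalties: tuple[float, float]
    combination_rule: str

    @property
    def mu(self) -> pd.Series:
        return self.frame["mu"]


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join(rng.choice(_BASES, size=length))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def _position_guides(
    rng: np.random.Generator, config: SimulationConfig, nuclease: str, position: int
) -> list[GuideRecord]:
    genes = [f"CE{i+1:02d}" for i in range(config.n_ce)] + [
        f"TS{i+1:02d}" for i in range(config.n_ts)
    ]
    n = len(genes) * config.guides_per_gene + config.n_nht
    spacers = _random_spacers(rng, n, SPACER_LEN[nuclease])
    guides: list[GuideRecord] = []
    k = 0
    for gene in genes:
        cls = "CE" if gene.startswith("CE") else "TS"
        for rank in range(1, config.guides_per_gene + 1):
            guides.append(
                GuideRecord(
                    guide_id=f"p{position}_{gene}_g{rank}",
                    nuclease=nuclease,
                    spacer=spacers[k],
                    gene=gene,
                    gene_class=cls,
                    rank=rank,
                    pam_context=_pam(rng, nuclease, config.tttv_fraction),
                )
            )
            k += 1
    for i in range(config.n_nht):
        guides.append(
            GuideRecord(
                guide_id=f"p{position}_NHT_{i+1:03d}",
                nuclease=nuclease,
                spacer=spacers[k],
                gene="NHT",
                gene_class="NHT",
                pam_context=_pam(rng, nuclease, config.tttv_fraction),
            )
        )
        k += 1
    return guides


def _pam(rng: np.random.Generator, nuclease: str, tttv_fraction: float) -> str | None:
    if nuclease != "AsCas12a":
        return None
    if rng.random() < tttv_fraction:
        return "TTT" + rng.choice(["A", "C", "G"])
    return "".join(rng.choice(_BASES, size=3)) + rng.choice(_BASES)


def synthetic_library(config: SimulationConfig, seed: int) -> CombinatorialLibrary:
    """Generate the design's combinatorial library with synthetic spacers.

    Synthetic stand-in for a real guide-library table: gene symbols are
    CE01..CE10 / TS01..TS10, spacers are random DNA of the correct
    per-nuclease length, AsCas12a guides get mostly-TTTV PAM contexts.
    """
    design = get_design(config.design)
    rng = np.random.default_rng(seed)
    g1 = _position_guides(rng, config, design.cassette1_nuclease, 1)
    g2 = _position_guides(rng, config, design.cassette2_nuclease, 2)
    return build_library(g1, g2, design)


def _gene_fitness(rng: np.random.Generator, config: SimulationConfig) -> pd.Series:
    vals = {}
    for i in range(config.n_ce):
        mean, sd = config.f_ce
        if i >= config.n_ce_gold:
            mean, sd = mean * config.f_weak_scale, sd * config.f_weak_scale
        vals[f"CE{i+1:02d}"] = rng.normal(mean, sd)
    for i in range(config.n_ts):
        mean, sd = config.f_ts
        if i >= config.n_ts_gold:
            mean, sd = mean * config.f_weak_scale, sd * config.f_weak_scale
        vals[f"TS{i+1:02d}"] = rng.normal(mean, sd)
    vals["NHT"] = 0.0
    return pd.Series(vals, name="fitness")


def synthetic_gold_standard(config: SimulationConfig):
    """Gold standard matching the simulator's fitness model: the strong-effect
    genes are positives, the weak-effect remainder is the negative class."""
    from .evaluation import GoldStandard

    n_ce_gold = min(config.n_ce_gold, config.n_ce)
    n_ts_gold = min(config.n_ts_gold, config.n_ts)
    ce = frozenset(f"CE{i+1:02d}" for i in range(n_ce_gold))
    ts = frozenset(f"TS{i+1:02d}" for i in range(n_ts_gold))
    neg = frozenset(
        [f"CE{i+1:02d}" for i in range(n_ce_gold, config.n_ce)]
        + [f"TS{i+1:02d}" for i in range(n_ts_gold, config.n_ts)]
    )
    return GoldStandard(ce, ts, neg, source="simulation ground truth")


def _effective_activity(
    rng: np.random.Generator, config: SimulationConfig, guides: list[GuideRecord], dual: bool
) -> pd.Series:
    lo, hi = config.activity_range
    a, b = config.activity_beta

    def draw(size: int) -> np.ndarray:
        return lo + (hi - lo) * rng.beta(a, b, size=size)

    base = draw(len(guides))
    if dual:
        # arrayed dual-gRNAs: the slot cuts if either of its two guides does
        second = draw(len(guides))
        base = 1.0 - (1.0 - base) * (1.0 - second)
    return pd.Series(base, index=[g.guide_id for g in guides], name="activity")


def draw_true_effects(
    library: CombinatorialLibrary, config: SimulationConfig, seed: int
) -> TrueEffects:
    """Draw gene fitness and guide activities; compute per-combination mu.

    NHT guides contribute zero fitness effect by construction (their spacers
    exist for quantification, their f is 0).  In dual-gene-array designs the
    effective activity of AsCas12a slots combines two same-gene guides as
    a_eff = 1 - (1-a1)(1-a2).
    """
    design = library.design
    rng = np.random.default_rng(seed)
    fitness = _gene_fitness(rng, config)
    dual1 = design.dual_gene_arrays and design.cassette1_nuclease == "AsCas12a"
    dual2 = design.dual_gene_arrays and design.cassette2_nuclease == "AsCas12a"
    act1 = _effective_activity(rng, config, library.guides_pos1, dual1)
    act2 = _effective_activity(rng, config, library.guides_pos2, dual2)
    activity = pd.concat([act1, act2])

    combos = library.combos
    f_a = fitness.loc[combos["gene_a"]].to_numpy()
    f_b = fitness.loc[combos["gene_b"]].to_numpy()
    a1 = act1.loc[combos["guide_a"]].to_numpy()
    a2 = act2.loc[combos["guide_b"]].to_numpy()
    frame = pd.DataFrame(
        {"contrib1": f_a * a1, "contrib2": f_b * a2}, index=combos.index
    )
    both_target = (combos["class_a"] != "NHT") & (combos["class_b"] != "NHT")
    frame["interaction"] = np.where(both_target, config.interaction, 0.0)
    effects = TrueEffects(
        gene_fitness=fitness,
        guide_activity=activity,
        frame=frame,
        doublings=config.doublings,
        penalties=design.processing_penalty_defaults,
        combination_rule=config.combination_rule,
    )
    _recompute_mu(effects)
    return effects


def _recompute_mu(effects: TrueEffects) -> None:
    p1, p2 = effects.penalties
    c1 = effects.frame["contrib1"] * p1
    c2 = effects.frame["contrib2"] * p2
    if effects.combination_rule == "additive":
        combined = c1 + c2
    else:  # max: the stronger (most extreme) single contribution wins
        combined = pd.Series(
            np.where(c1.abs() >= c2.abs(), c1, c2), index=effects.frame.index
        )
    effects.frame["mu"] = effects.doublings * (combined + effects.frame["interaction"])


def apply_design_penalty(
    effects: TrueEffects, design: LibraryDesign | str | tuple[float, float]
) -> TrueEffects:
    """Re-derive mu under another design's processing penalties.

    Accepts a design name, a LibraryDesign, or an explicit (pi1, pi2) pair.
    (1, 1) is the identity; (0, 1) silences position 1 entirely.
    """
    if isinstance(design, str):
        penalties = get_design(design).processing_penalty_defaults
    elif isinstance(design, LibraryDesign):
        penalties = design.processing_penalty_defaults
    else:
        penalties = (float(design[0]), float(design[1]))
    for p in penalties:
        if not 0 <= p <= 1:
            raise ValueError("penalties must lie in [0, 1]")
    out = TrueEffects(
        gene_fitness=effects.gene_fitness.copy(),
        guide_activity=effects.guide_activity.copy(),
        frame=effects.frame[["contrib1", "contrib2", "interaction"]].copy(),
        doublings=effects.doublings,
        penalties=penalties,
        combination_rule=effects.combination_rule,
    )
    _recompute_mu(out)
    return out


def simulate_counts(
    effects: TrueEffects,
    config: SimulationConfig,
    seed: int,
    *,
    noiseless: bool = False,
) -> CountTable:
    """Sample a library-reference + end-replicate count table.

    Initial relative abundances are lognormal(0, initial_sigma) (lentiviral
    representation skew), normalized to 1.  The reference sample is a
    multinomial draw at depth; each end replicate is a multinomial draw from
    abundances reweighted by 2^mu.  ``noiseless`` returns the exact expected
    (real-valued) counts with no representation skew sampling noise on the
    draws (the skew itself is still drawn so the reference is non-trivial).
    """
    rng = np.random.default_rng(seed)
    n = len(effects.frame)
    depth = config.effective_depth(n)
    if depth < n:
        import warnings

        warnings.warn(f"depth {depth} below library size {n} (sub-coverage)", stacklevel=2)
    initial = rng.lognormal(mean=0.0, sigma=config.initial_sigma, size=n)
    initial = initial / initial.sum()
    mu = effects.mu.to_numpy()
    end_p = initial * np.exp2(mu)
    end_p = end_p / end_p.sum()

    def draw(p: np.ndarray) -> np.ndarray:
        if noiseless:
            return depth * p
        if config.overdispersion is not None:
            p = rng.dirichlet(p * config.overdispersion)
        return rng.multinomial(depth, p)

    cols = {"library": draw(initial)}
    roles = [("library", "library_reference", 0)]
    for r in range(1, config.replicates + 1):
        cols[f"end_rep{r}"] = draw(end_p)
        roles.append((f"end_rep{r}", "screen_end", r))
    counts = pd.DataFrame(cols, index=effects.frame.index)
    if not noiseless:
        counts = counts.astype(np.int64)
    samples = pd.DataFrame(
        [{"sample_id": s, "role": role, "replicate": rep} for s, role, rep in roles]
    ).set_index("sample_id")
    return CountTable(counts, samples)


def simulate_screen(
    config: SimulationConfig, seed: int, *, noiseless: bool = False
) -> tuple[CombinatorialLibrary, TrueEffects, CountTable]:
    """Library + ground truth + counts in one call (sub-seeds derived from seed)."""
    ss = np.random.SeedSequence(seed).spawn(3)
    lib_seed, eff_seed, cnt_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    library = synthetic_library(config, lib_seed)
    effects = draw_true_effects(library, config, eff_seed)
    counts = simulate_counts(effects, config, cnt_seed, noiseless=noiseless)
    return library, effects, counts


def emit_reads(
    counts: CountTable,
    library: CombinatorialLibrary,
    anchor1: str,
    anchor2: str,
    *,
    sample_id: str | None = None,
    read_len: int = 60,
    seed: int = 0,
    error_rate: float = 0.0,
) -> tuple[list[str], list[str]]:
    """Emit synchronized paired reads realizing one sample's counts.

    For each combination with count c, exactly c read pairs are produced:
    anchor + spacer + random tail, padded to ``read_len``, in a deterministic
    shuffled order.  ``error_rate`` injects independent substitutions per base
    across the whole read.
    """
    if sample_id is None:
        if len(counts.sample_ids) != 1:
            raise ValueError("table has several samples; pass sample_id")
        sample_id = counts.sample_ids[0]
    col = counts.counts[sample_id]
    if not np.allclose(col, np.round(col)):
        raise ValueError("emit_reads needs integer counts (not a noiseless table)")
    spac1 = {g.guide_id: g.spacer for g in library.guides_pos1}
    spac2 = {g.guide_id: g.spacer for g in library.guides_pos2}
    len1 = len(anchor1) + library.design.spacer_lengths[0]
    len2 = len(anchor2) + library.design.spacer_lengths[1]
    if read_len < max(len1, len2):
        raise ValueError(f"read_len {read_len} too short for anchor+spacer ({max(len1, len2)})")
    rng = np.random.default_rng(seed)
    combos = library.combos
    nonzero = col[col > 0]
    order = np.repeat(np.arange(len(nonzero)), nonzero.astype(int).to_numpy())
    rng.shuffle(order)
    ga = combos.loc[nonzero.index, "guide_a"].to_numpy()
    gb = combos.loc[nonzero.index, "guide_b"].to_numpy()

    def finish(core: str) -> str:
        tail = read_len - len(core)
        read = core + "".join(rng.choice(_BASES, size=tail))
        if error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
            for h in hits:
                choices = [b for b in b"ACGT" if b != arr[h]]
                arr[h] = choices[rng.integers(3)]
            read = arr.tobytes().decode()
        return read

    r1: list[str] = []
    r2: list[str] = []
    for k in order:
        r1.append(finish(anchor1 + spac1[ga[k]]))
        r2.append(finish(anchor2 + spac2[gb[k]]))
    return r1, r2
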