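"""Generative model of a pooled shRNA viability screen.

The screen is modeled as a chain of sampling bottlenecks, each of which
discards information about the true per-hairpin abundances:

1. **Transduction** — ``round(S*C)`` independent integrations are drawn
   multinomially from the plasmid-pool proportions, where ``S`` is the
   pool size and ``C`` the average fold representation (integrations
   per shRNA).  The MOI is kept low (0.3) so a single integration per
   genome can be assumed; it enters the arithmetic only through that
   assumption, not through infection kinetics.
2. **Selection** — cells grow for 14 days under puromycin.  Each day a
   cell carrying hairpin *i* divides at rate ``g0 + f_i`` where ``f_i``
   is the hairpin's fitness effect (0 for most hairpins); growth is a
   Poisson branching step and confluent cultures are passaged 1:4 by
   binomial thinning.  The expected relative abundance of hairpin *i*
   after *d* days is proportional to ``t0_i * exp(f_i * d)``.
3. **gDNA aliquot** — a multinomial subsample of ``round(S*T)``
   template molecules, where ``T`` is the average template copies per
   shRNA carried into PCR.
4. **PCR** — a per-molecule Galton-Watson branching process: at each
   cycle a molecule duplicates with probability ``e_eff``, where
   ``e_eff = e0 * min(1, K/total)`` decays once the total molecule
   count exceeds the reaction capacity ``K`` (sharp exponential-to-
   linear transition; a logistic law is available as an alternative).
   Per-tube, per-clone efficiency jitter models sequence-context
   amplification bias, which compounds over cycles.
5. **Readout** — sequencing (multinomial reads over proportions,
   optional FASTQ emission) or two-channel microarray (per-probe log2
   intensities with Gaussian noise and a background floor).

All randomness flows from one master seed through named substreams:
biological replicates re-draw transduction and selection; technical
replicates re-draw only aliquot, PCR and readout.
"""

from __future__ import annotations

import gzip
import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from poolscreen.library import LibrarySpec

LN2 = math.log(2.0)


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from a master seed.

    Each distinct key tuple yields an independent stream; the same
    (seed, keys) always yields the same stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        h = hashlib.sha256(repr(k).encode()).digest()
        entropy.append(int.from_bytes(h[:8], "little"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class ScreenParams:
    """Tunable parameters of the screen, with the study conditions as defaults.

    Attributes
    ----------
    fold_representation
        Average independent integrations per shRNA at transduction (C).
    moi
        Multiplicity of infection; kept at 0.3 so a median single
        integration per genome holds.  Accounting only.
    selection_days
        Days of selection between the reference (T0) and test (T1)
        harvests.
    passage_ratio
        Fraction of cells kept at each passage (1:4 split = 0.25).
    passage_trigger
        Passage when the population exceeds this multiple of the
        starting population (a proxy for confluency).
    baseline_growth
        Per-day log growth rate of a neutral cell (ln 2 = one doubling
        per day).
    fitness_effects
        Optional per-shRNA growth-rate deltas (per day).  When None,
        effects are drawn per screen: 0 with probability
        ``1 - frac_affected``, otherwise Normal(0, ``effect_sd``).
    frac_affected, effect_sd
        Parameters of the drawn fitness prior.  The default sd of
        0.1/day over 14 days gives affected hairpins a log2 fold-change
        spread of about 2.
    pcr_cycles
        High-fidelity amplification cycles (23 = last exponential
        cycle under the optimized protocol).
    template_copies
        Average template copies per shRNA in the PCR input.
    pcr_efficiency
        Per-cycle duplication probability e0 in the exponential phase.
    pcr_efficiency_sd
        Relative sd of per-tube per-clone efficiency (amplification
        bias that compounds over cycles).
    pcr_capacity
        Molecule count at which amplification saturates.  When None it
        is set to ``input_total * 2**pcr_saturation_cycle`` so that a
        reaction loaded at the protocol's fixed per-reaction template
        mass leaves the exponential phase near ``pcr_saturation_cycle``.
    reads_per_sample
        Sequencing depth per sample (89 million 50-bp reads per lane
        for a ~10 000 pool = 8 900 reads per shRNA).
    array_noise_sd, array_probes_per_clone, array_scale, array_background
        Microarray noise model: per-probe log2 intensities around
        log2(proportion * scale), floored at log2(background).
    seed
        Master seed; all stage randomness derives from it.
    """

    fold_representation: float = 100.0
    moi: float = 0.3
    n_cells: int | None = None
    selection_days: int = 14
    passage_ratio: float = 0.25
    passage_trigger: float = 4.0
    baseline_growth: float = LN2
    fitness_effects: np.ndarray | None = None
    frac_affected: float = 0.05
    effect_sd: float = 0.1
    pcr_cycles: int = 23
    template_copies: float = 100.0
    pcr_efficiency: float = 0.98
    pcr_efficiency_sd: float = 0.01
    pcr_capacity: float | None = None
    pcr_saturation_cycle: int = 23
    saturation_model: str = "step"
    reads_per_sample: int = 89_000_000
    array_noise_sd: float = 0.25
    array_probes_per_clone: int = 4
    array_scale: float = 1e6
    array_background: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_representation <= 0:
            raise ValueError("fold_representation must be positive")
        if self.moi <= 0:
            raise ValueError("moi must be positive")
        if not 0.0 <= self.pcr_efficiency <= 1.0:
            raise ValueError("pcr_efficiency must lie in [0, 1]")
        if self.pcr_capacity is not None and self.pcr_capacity <= 0:
            raise ValueError("pcr_capacity must be positive")
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be nonnegative")
        if not 0.0 < self.passage_ratio <= 1.0:
            raise ValueError("passage_ratio must lie in (0, 1]")
        if self.saturation_model not in ("step", "logistic"):
            raise ValueError("saturation_model must be 'step' or 'logistic'")


STAGES = ("plasmid", "integrated", "T0", "T1", "gdna_aliquot", "post_pcr", "reads")


@dataclass
class StageCounts:
    """Per-shRNA molecule (or read) counts at one stage of the screen."""

    stage: str
    counts: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if np.any(self.counts < 0):
            raise ValueError("stage counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError(f"stage {self.stage!r} went extinct; no proportions")
        return self.counts / tot


def draw_fitness_effects(
    pool_size: int,
    frac_affected: float = 0.05,
    effect_sd: float = 0.1,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-shRNA growth-rate deltas: a point mass at zero for most
    hairpins, Normal(0, effect_sd) for the affected minority."""
    rng = _as_rng(rng)
    effects = np.zeros(pool_size)
    affected = rng.random(pool_size) < frac_affected
    effects[affected] = rng.normal(0.0, effect_sd, size=int(affected.sum()))
    return effects


def simulate_transduction(
    lib: LibrarySpec,
    params: ScreenParams,
    rng: int | np.random.Generator | None = None,
) -> StageCounts:
    """Draw integrated proviral copies at transduction.

    The total number of integrations is ``round(S*C)``; they are
    distributed multinomially over the plasmid-pool proportions, so the
    expected copy number of hairpin *i* is ``S*C*plasmid_props[i]``.
    """
    rng = _as_rng(rng)
    s = lib.pool_size
    if s == 0:
        raise ValueError("empty library")
    total = int(round(s * params.fold_representation))
    if total <= 0:
        raise ValueError("S*C must round to a positive integration count")
    counts = rng.multinomial(total, lib.plasmid_props)
    return StageCounts(stage="integrated", counts=counts)


def simulate_selection(
    t0: StageCounts,
    params: ScreenParams,
    rng: int | np.random.Generator | None = None,
    deterministic: bool = False,
) -> StageCounts:
    """Grow the transduced population for ``selection_days`` days.

    Each day the count of hairpin *i* is resampled as
    ``Poisson(n_i * exp(g0 + f_i))``; when the population exceeds
    ``passage_trigger`` times its starting size it is passaged by
    binomial thinning with ``passage_ratio``.  Expected relative
    abundance after *d* days is proportional to ``t0_i*exp(f_i*d)``.

    With ``deterministic=True`` the closed-form expectation is returned
    (rounded), holding the total at the starting population size.
    """
    rng = _as_rng(rng)
    fitness = params.fitness_effects
    if fitness is None:
        fitness = np.zeros(len(t0.counts))
    fitness = np.asarray(fitness, dtype=float)
    if fitness.shape != t0.counts.shape:
        raise ValueError("fitness_effects length must match the pool size")

    if deterministic:
        weights = t0.counts * np.exp(fitness * params.selection_days)
        expected = weights / weights.sum() * t0.total
        return StageCounts(stage="T1", counts=np.round(expected).astype(np.int64))

    counts = t0.counts.astype(np.int64)
    start_total = counts.sum()
    trigger = params.passage_trigger * start_total
    growth = np.exp(params.baseline_growth + fitness)
    for _ in range(params.selection_days):
        counts = rng.poisson(counts * growth)
        while counts.sum() > trigger:
            counts = rng.binomial(counts, params.passage_ratio)
    return StageCounts(stage="T1", counts=counts)


def simulate_gdna_aliquot(
    t: StageCounts,
    template_copies: float,
    rng: int | np.random.Generator | None = None,
) -> StageCounts:
    """Subsample the gDNA carried into PCR.

    Draws ``round(S * template_copies)`` template molecules
    multinomially (with replacement) from the stage proportions; the
    per-shRNA counts are therefore Poisson-like with mean
    ``template_copies`` for an even pool.
    """
    rng = _as_rng(rng)
    if template_copies <= 0:
        raise ValueError("template_copies must be positive")
    size = int(round(len(t.counts) * template_copies))
    if size <= 0:
        raise ValueError("aliquot of size 0")
    counts = rng.multinomial(size, t.proportions)
    return StageCounts(stage="gdna_aliquot", counts=counts, replicate=t.replicate)


def simulate_pcr(
    aliquot: StageCounts,
    cycles: int = 23,
    e0: float = 0.98,
    capacity: float | None = None,
    efficiency_sd: float = 0.0,
    saturation_cycle: int = 23,
    saturation_model: str = "step",
    deterministic: bool = False,
    rng: int | np.random.Generator | None = None,
) -> StageCounts:
    """Amplify an aliquot as a per-molecule branching process.

    At each cycle every molecule of hairpin *i* duplicates with
    probability ``e_i * sat(total)`` where ``e_i`` is the tube's
    per-clone efficiency (``e0`` with optional relative jitter
    ``efficiency_sd`` drawn once per tube) and ``sat`` is the
    saturation law: ``min(1, K/total)`` (step, default) or
    ``K/(K+total)`` (logistic).  When ``capacity`` is None it is set to
    ``input_total * 2**saturation_cycle``, reflecting a protocol that
    fixes the template mass per reaction so the exponential phase ends
    near ``saturation_cycle`` regardless of how many tubes are run.

    With ``deterministic=True``, counts are scaled by ``1 + e_eff``
    each cycle without branching noise.
    """
    if cycles < 0:
        raise ValueError("cycles must be nonnegative")
    if not 0.0 <= e0 <= 1.0:
        raise ValueError("PCR efficiency must lie in [0, 1]")
    rng = _as_rng(rng)
    start_total = aliquot.counts.sum()
    if capacity is None:
        capacity = float(start_total) * 2.0**saturation_cycle
    if capacity <= 0:
        raise ValueError("capacity must be positive")

    e_clone = np.full(len(aliquot.counts), e0, dtype=float)
    if efficiency_sd > 0:
        e_clone = np.clip(e0 * (1.0 + rng.normal(0.0, efficiency_sd, size=len(e_clone))), 0.0, 1.0)

    if deterministic:
        counts = aliquot.counts.astype(float)
        for _ in range(cycles):
            total = counts.sum()
            sat = _saturation(total, capacity, saturation_model)
            counts = counts * (1.0 + e_clone * sat)
        return StageCounts(
            stage="post_pcr", counts=np.round(counts).astype(np.int64), replicate=aliquot.replicate
        )

    counts = aliquot.counts.astype(np.int64)
    for _ in range(cycles):
        total = counts.sum()
        sat = _saturation(total, capacity, saturation_model)
        counts = counts + rng.binomial(counts, np.clip(e_clone * sat, 0.0, 1.0))
    return StageCounts(stage="post_pcr", counts=counts, replicate=aliquot.replicate)


def _saturation(total: float, capacity: float, model: str) -> float:
    if model == "step":
        return min(1.0, capacity / total) if total > 0 else 1.0
    if model == "logistic":
        return capacity / (capacity + total)
    raise ValueError(f"unknown saturation model {model!r}")


def simulate_readout(
    post_pcr: StageCounts,
    mode: str,
    params: ScreenParams,
    rng: int | np.random.Generator | None = None,
) -> pd.Series | pd.DataFrame:
    """Measure the amplified material.

    ``mode="sequencing"`` draws ``reads_per_sample`` reads multinomially
    over the stage proportions and returns an integer Series of counts.

    ``mode="microarray"`` returns a DataFrame of per-probe log2
    intensities (``array_probes_per_clone`` columns): log2 of the
    clone's scaled abundance plus Normal(0, ``array_noise_sd``) noise,
    floored at log2 of the background.
    """
    rng = _as_rng(rng)
    if mode == "sequencing":
        if params.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be nonnegative")
        if params.reads_per_sample == 0:
            counts = np.zeros(len(post_pcr.counts), dtype=np.int64)
        else:
            counts = rng.multinomial(params.reads_per_sample, post_pcr.proportions)
        return pd.Series(counts, name=post_pcr.replicate)
    if mode == "microarray":
        props = post_pcr.proportions
        true_log2 = np.log2(props * params.array_scale + params.array_background)
        k = params.array_probes_per_clone
        noise = (
            rng.normal(0.0, params.array_noise_sd, size=(len(props), k))
            if params.array_noise_sd > 0
            else np.zeros((len(props), k))
        )
        intensity = true_log2[:, None] + noise
        floor = np.log2(params.array_background) if params.array_background > 0 else -np.inf
        intensity = np.maximum(intensity, floor)
        return pd.DataFrame(intensity, columns=[f"probe_{j + 1}" for j in range(k)])
    raise ValueError(f"unknown readout mode {mode!r}")


def reads_to_fastq(
    counts: pd.Series | np.ndarray,
    lib: LibrarySpec,
    path,
    read_len: int = 50,
    rng: int | np.random.Generator | None = None,
) -> int:
    """Write simulated reads to a FASTQ file (gzipped if path ends .gz).

    Each hairpin with count *c* emits *c* error-free reads of its first
    ``read_len`` bases, in shuffled order; returns the read count.
    """
    if lib.hairpin_seqs is None:
        raise ValueError("library has no hairpin sequences")
    rng = _as_rng(rng)
    counts = np.asarray(counts)
    idx = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(idx)
    qual = "I" * read_len
    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for r, i in enumerate(idx):
            fh.write(f"@read_{r} {lib.shrna_ids[i]}\n{lib.hairpin_seqs[i][:read_len]}\n+\n{qual}\n")
            n += 1
    return n


@dataclass
class ScreenResult:
    """Simulated screen: count/intensity data plus ground truth."""

    counts: pd.DataFrame
    truth: pd.DataFrame
    array_probes: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: ScreenParams | None = None


def sample_name(condition: str, bio_rep: str, tech_rep: int) -> str:
    """Canonical sample label, e.g. ``T1_A_1``."""
    return f"{condition}_{bio_rep}_{tech_rep}"


def simulate_screen(
    lib: LibrarySpec,
    params: ScreenParams,
    n_bio: int = 2,
    n_tech: int = 1,
    mode: str = "sequencing",
) -> ScreenResult:
    """Run the full screen: transduction, selection, and deconvolution.

    Biological replicates (labeled A, B, ...) re-draw transduction and
    selection; technical replicates re-draw only the gDNA aliquot, PCR
    and readout.  The reference sample T0 is deconvolved from the
    integrated population, the test sample T1 from the population after
    ``selection_days`` of selection.

    Returns a :class:`ScreenResult` whose ``counts`` DataFrame holds
    one column per sample (sequencing counts, or per-clone mean probe
    intensity for arrays; per-probe arrays are kept in
    ``array_probes``) and whose ``truth`` DataFrame records the plasmid
    proportions and fitness effects.
    """
    seed = params.seed
    fitness = params.fitness_effects
    if fitness is None:
        fitness = draw_fitness_effects(
            lib.pool_size, params.frac_affected, params.effect_sd, substream(seed, "fitness")
        )
    params = replace(params, fitness_effects=fitness)

    columns: dict[str, np.ndarray] = {}
    probes: dict[str, pd.DataFrame] = {}
    for b in range(n_bio):
        bio = chr(ord("A") + b)
        t0 = simulate_transduction(lib, params, substream(seed, "transduction", bio))
        t0 = StageCounts("T0", t0.counts, replicate=bio)
        t1 = simulate_selection(t0, params, substream(seed, "selection", bio))
        t1 = StageCounts("T1", t1.counts, replicate=bio)
        for cond, pop in (("T0", t0), ("T1", t1)):
            for t in range(1, n_tech + 1):
                name = sample_name(cond, bio, t)
                rng = substream(seed, "tech", bio, cond, t)
                aliquot = simulate_gdna_aliquot(pop, params.template_copies, rng)
                post = simulate_pcr(
                    aliquot,
                    cycles=params.pcr_cycles,
                    e0=params.pcr_efficiency,
                    capacity=params.pcr_capacity,
                    efficiency_sd=params.pcr_efficiency_sd,
                    saturation_cycle=params.pcr_saturation_cycle,
                    saturation_model=params.saturation_model,
                    rng=rng,
                )
                out = simulate_readout(post, mode, params, rng)
                if mode == "microarray":
                    probes[name] = out.set_axis(lib.shrna_ids, axis=0)
                    columns[name] = out.mean(axis=1).to_numpy()
                else:
                    columns[name] = out.to_numpy()

    counts = pd.DataFrame(columns, index=lib.shrna_ids)
    truth = pd.DataFrame(
        {"plasmid_prop": lib.plasmid_props, "fitness": fitness}, index=lib.shrna_ids
    )
    return ScreenResult(counts=counts, truth=truth, array_probes=probes, params=params)


def simulate_cq_panel(
    true_transition_cycle: int = 23,
    e0: float = 1.0,
    sybr_efficiency_pct: float = 100.0,
    dilutions: tuple[float, ...] = (25_000, 100_000, 400_000),
    replicates: int = 4,
    stop_cycles: range | tuple[int, ...] = range(15, 28),
    noise_sd: float = 0.0,
    post_transition_decay: float = 0.6,
    cq_offset: float = 20.0,
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit a stop-cycle qPCR panel for exponential-phase detection.

    Replicate high-fidelity PCR reactions are stopped at each cycle in
    ``stop_cycles``; the product of each is serially diluted and
    measured by SYBR qPCR.  Product grows by ``1 + e0`` per cycle up to
    ``true_transition_cycle`` and by ``1 + e0 * decay**(n - transition)``
    after it (gradual loss of doubling).  The Cq of a well is the
    cycle at which the diluted template crosses threshold under the
    stated SYBR primer efficiency, plus Gaussian replicate noise.

    Returns a tidy DataFrame with columns
    ``stop_cycle, dilution, replicate, cq``.
    """
    if not dilutions:
        raise ValueError("at least one dilution is required")
    if not 0.0 < sybr_efficiency_pct <= 100.0:
        raise ValueError("SYBR efficiency must lie in (0, 100]")
    rng = _as_rng(rng)
    stop_cycles = list(stop_cycles)
    log2_sybr = math.log2(1.0 + sybr_efficiency_pct / 100.0)

    # cumulative product amount, in doublings (log2 units)
    log2_amount = {}
    acc = 0.0
    for n in range(1, max(stop_cycles) + 1):
        if n <= true_transition_cycle:
            eff = e0
        else:
            eff = e0 * post_transition_decay ** (n - true_transition_cycle)
        acc += math.log2(1.0 + eff)
        log2_amount[n] = acc

    rows = []
    for n in stop_cycles:
        for d in dilutions:
            # Cq in SYBR cycles: template = amount/dilution
            cq0 = cq_offset + (math.log2(d) - log2_amount[n]) / log2_sybr
            for r in range(1, replicates + 1):
                cq = cq0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((n, d, r, cq))
    panel = pd.DataFrame(rows, columns=["stop_cycle", "dilution", "replicate", "cq"])
    if (panel["cq"] <= 0).any():
        raise ValueError("panel produced nonpositive Cq; increase cq_offset")
    return panel
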