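"""Template-representation arithmetic for screen deconvolution PCR.

Assuming a single proviral integration per genome, the number of shRNA
template copies in a gDNA mass is simply the number of genome copies in
that mass.  These helpers convert between gDNA mass, template copies,
copies per shRNA, and the number of fixed-mass PCR reactions needed to
maintain a target fold representation through amplification.

With the default diploid human genome mass of 6.6 pg, one 825 ng
reaction carries 125 000 template copies — 12.5 copies per shRNA for a
10 000-construct pool — so maintaining 100 copies per shRNA requires
eight reactions (6.6 µg total) and 500 copies requires forty (33 µg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

AVOGADRO = 6.022e23  # mol^-1
DEFAULT_BP_MASS = 650.0  # g/mol per base pair
DEFAULT_GENOME_PG = 6.6  # diploid human genome, pg


@dataclass
class GenomeModel:
    """Mass model of the template genome.

    Either set ``genome_mass_pg`` directly (default 6.6 pg, diploid
    human) or leave it None to derive it from ``bp_count`` base pairs
    at ``mass_per_bp`` g/mol via Avogadro's number.
    """

    bp_count: float | None = None
    mass_per_bp: float = DEFAULT_BP_MASS
    avogadro: float = AVOGADRO
    genome_mass_pg: float | None = DEFAULT_GENOME_PG

    def __post_init__(self) -> None:
        if self.genome_mass_pg is None:
            if self.bp_count is None or self.bp_count <= 0:
                raise ValueError("need bp_count when genome_mass_pg is unset")
            self.genome_mass_pg = self.bp_count * self.mass_per_bp / self.avogadro * 1e12
        if self.genome_mass_pg <= 0:
            raise ValueError("genome mass must be positive")


@dataclass
class RepresentationSpec:
    """A PCR plan maintaining ``copies_per_shrna`` for a pool of ``pool_size``."""

    pool_size: int
    copies_per_shrna: float
    per_reaction_mass_ng: float
    n_reactions: int
    total_mass_ng: float


def copies_in_mass(mass_ng: float, gm: GenomeModel | None = None) -> float:
    """Template copies in ``mass_ng`` of gDNA (one copy per genome)."""
    if mass_ng < 0:
        raise ValueError("mass must be nonnegative")
    gm = gm or GenomeModel()
    genome_mass_ng = gm.genome_mass_pg * 1e-3
    return mass_ng / genome_mass_ng


def copies_per_shrna(copies: float, pool_size: int) -> float:
    """Average template copies per shRNA for a pool of ``pool_size``."""
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    return copies / pool_size


def plan_reactions(
    pool_size: int,
    fold_representation: float,
    per_reaction_mass_ng: float = 825.0,
    gm: GenomeModel | None = None,
) -> RepresentationSpec:
    """Number of fixed-mass PCR reactions needed to carry
    ``pool_size * fold_representation`` template copies.

    Uses the ceiling — representation is a floor guarantee, so a
    partial reaction rounds up.
    """
    if pool_size <= 0 or fold_representation <= 0 or per_reaction_mass_ng <= 0:
        raise ValueError("pool size, fold representation and reaction mass must be positive")
    per_reaction_copies = copies_in_mass(per_reaction_mass_ng, gm)
    n = math.ceil(pool_size * fold_representation / per_reaction_copies)
    return RepresentationSpec(
        pool_size=pool_size,
        copies_per_shrna=fold_representation,
        per_reaction_mass_ng=per_reaction_mass_ng,
        n_reactions=n,
        total_mass_ng=n * per_reaction_mass_ng,
    )


def reads_per_shrna(total_reads: float, pool_size: int) -> float:
    """Average sequencing reads per shRNA."""
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    return total_reads / pool_size
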