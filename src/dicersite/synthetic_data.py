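"""Synthetic pre-miRNA hairpins with planted cleavage determinants.

Real pre-miRNAs are ~60-120 nt stem-loops carrying two Dicer cleavage
sites whose positions correlate with local sequence and structure.  This
module emulates that geometry so the whole pipeline — annotation parsing,
pattern generation, encoding, training — is exercisable without any
downloads:

* sequence = random 5' arm + loop + a reverse-complement-biased 3' arm, so
  the paired-stem dot-bracket structure is plausible;
* structure = "("*stem + "."*loop + ")"*stem with symmetric unpaired
  bulges inserted at a configurable rate (bracket balance preserved);
* two cleavage sites placed 20-30 intervals from either end (mature-arm
  geometry), separated widely enough that no configured window can span
  both;
* a short sequence motif written immediately 5' of each site, mutated
  per-position with probability ``noise``.  At noise=0 the motif appears
  verbatim and the interval class of every window is decodable from the
  motif position — a learnable signal; at noise=1 the motif positions are
  uniform random and the signal is gone.

Mature-arm annotations are emitted consistent with the cleavage-site
convention (5p site = end of 5p mature; 3p site = start of 3p mature - 1),
so round-tripping through annotation inference recovers the planted sites.
No claim of biological realism is made beyond this geometry.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io_formats import (
    MatureAnnotation,
    SequenceRecord,
    StructureRecord,
    ValidationError,
    write_fasta,
    write_mature_annotation,
    write_structures,
)
from .pattern_engine import CleavageSite, PreMiRNA

__all__ = ["SimParams", "simulate_hairpin", "simulate_corpus", "write_corpus"]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = np.array(list("ACGU"))


@dataclasses.dataclass(frozen=True)
class SimParams:
    """Generator settings.

    ``site_offset_range`` bounds both sites' distance (in intervals) from
    their respective hairpin end; with ``min_site_gap`` it guarantees every
    site sits at least s-1 intervals from the ends and the two sites are
    more than s-2 intervals apart for any pattern size s up to 18.
    """

    n_hairpins: int = 100
    length_range: tuple[int, int] = (60, 120)
    stem_pairing_fraction: float = 0.9
    bulge_rate: float = 0.08
    loop_range: tuple[int, int] = (4, 8)
    motif: str = "GCUC"  # planted immediately 5' of each cleavage site
    site_offset_range: tuple[int, int] = (20, 30)
    min_site_gap: int = 17  # > s - 2 for the largest supported s (18)
    noise: float = 0.0  # per-position motif mutation probability
    mature_length: int = 22
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.site_offset_range
        if self.length_range[0] < 2 * lo + self.min_site_gap:
            raise ValidationError(
                f"minimum length {self.length_range[0]} too short for site "
                f"offsets >= {lo} with gap > {self.min_site_gap - 1}")
        if set(self.motif) - set("ACGU"):
            raise ValidationError("motif must be over the RNA alphabet")


def _random_rna(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def simulate_hairpin(params: SimParams, rng: np.random.Generator,
                     index: int = 0) -> tuple[PreMiRNA, list[MatureAnnotation]]:
    """Draw one hairpin plus its pair of mature-arm annotations."""
    L = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
    lo, hi = params.site_offset_range
    # rejection-sample offsets keeping the two sites > min_site_gap apart
    for _ in range(1000):
        off5 = int(rng.integers(lo, hi + 1))
        off3 = int(rng.integers(lo, hi + 1))
        g5, g3 = off5, L - off3
        if g3 - g5 >= params.min_site_gap:
            break
    else:
        raise ValidationError(f"cannot place sites in a {L}-nt hairpin")

    loop_len = int(rng.integers(params.loop_range[0], params.loop_range[1] + 1))
    stem = (L - loop_len) // 2
    loop_len = L - 2 * stem  # absorb odd lengths into the loop

    arm5 = _random_rna(rng, stem)
    loop = _random_rna(rng, loop_len)
    arm3 = []
    for base in reversed(arm5):
        if rng.random() < params.stem_pairing_fraction:
            arm3.append(_COMPLEMENT[base])
        else:
            arm3.append(str(rng.choice(_BASES)))
    seq = arm5 + loop + arm3

    structure = ["("] * stem + ["."] * loop_len + [")"] * stem
    # symmetric bulges: unpair a stem rung on both strands, keeping balance
    for i in range(stem):
        if rng.random() < params.bulge_rate:
            structure[i] = "."
            structure[L - 1 - i] = "."

    # plant the motif just 5' of each site (sequence positions g-m+1..g)
    m = len(params.motif)
    for g in (g5, g3):
        for j, ch in enumerate(params.motif):
            pos = g - m + j  # 0-based index of nucleotide (g - m + 1 + j)
            if rng.random() < params.noise:
                seq[pos] = str(rng.choice(_BASES))
            else:
                seq[pos] = ch

    premirna = PreMiRNA(
        id=f"syn-{index:04d}",
        sequence="".join(seq),
        structure="".join(structure),
        sites=[CleavageSite(g5, "5p"), CleavageSite(g3, "3p")],
    )
    annotations = [
        MatureAnnotation(premirna.id, "5p",
                         max(1, g5 - params.mature_length + 1), g5),
        MatureAnnotation(premirna.id, "3p",
                         g3 + 1, min(L, g3 + params.mature_length)),
    ]
    return premirna, annotations


def simulate_corpus(params: SimParams
                    ) -> tuple[list[PreMiRNA], list[MatureAnnotation]]:
    """Draw ``n_hairpins`` independent hairpins from a seeded generator."""
    rng = np.random.default_rng(params.seed)
    premirnas, annotations = [], []
    for i in range(params.n_hairpins):
        p, anns = simulate_hairpin(params, rng, index=i)
        premirnas.append(p)
        annotations.extend(anns)
    return premirnas, annotations


def write_corpus(premirnas: list[PreMiRNA], annotations: list[MatureAnnotation],
                 outdir: str | Path) -> dict[str, Path]:
    """Write the three files real data would occupy: FASTA, structures, TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "hairpins.fasta",
        "structures": outdir / "hairpins.dbn",
        "annotations": outdir / "mature_arms.tsv",
    }
    write_fasta([SequenceRecord(p.id, p.sequence) for p in premirnas],
                paths["fasta"])
    write_structures([StructureRecord(p.id, p.structure) for p in premirnas],
                     paths["structures"],
                     sequences={p.id: p.sequence for p in premirnas})
    write_mature_annotation(annotations, paths["annotations"])
    return paths
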