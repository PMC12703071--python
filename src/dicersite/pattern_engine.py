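"""Cleavage-site inference and sliding-window pattern generation.

A pre-miRNA hairpin of length L carries two Dicer cleavage sites, each
sitting on an inter-nucleotide *interval*: interval g lies between
nucleotides g and g+1 (1-based).  The 5' site is the gap just 3' of the 5p
mature arm's last nucleotide (g = end_5p); the 3' site is the gap just 5'
of the 3p mature arm's first nucleotide (g = start_3p - 1) — Dicer's two
cuts release the mature duplex ends.

Sliding a window of size s over the hairpin yields L - s + 1 cleavage
patterns.  Window a covers nucleotides a..a+s-1 and intervals a..a+s-2.
A window containing exactly one site at global interval g is labeled with
the local interval index k = g - a + 1 in {1..s-1}; a window with no site
is labeled 0 (negative); windows spanning both sites are removed so each
pattern holds at most one site.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
import subprocess
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    MatureAnnotation,
    SequenceRecord,
    StructureRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CleavageSite",
    "PreMiRNA",
    "PatternConfig",
    "CleavagePattern",
    "PatternDataset",
    "infer_cleavage_sites",
    "generate_patterns",
    "build_dataset1",
    "build_dataset2",
    "split_folds",
    "cluster_redundancy",
    "assemble_premirnas",
]


@dataclasses.dataclass(frozen=True)
class CleavageSite:
    """A Dicer cut on 1-based inter-nucleotide interval ``g``."""

    interval: int
    arm: str  # "5p" or "3p"


@dataclasses.dataclass
class PreMiRNA:
    id: str
    sequence: str
    structure: str
    sites: list[CleavageSite] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValidationError(
                f"{self.id!r}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PatternConfig:
    """Pattern size s and the implied s-class label space {0..s-1}."""

    s: int = 14
    max_seq_len: int = 200

    def __post_init__(self):
        if self.s < 4:
            raise ValidationError(f"pattern size must be >= 4, got {self.s}")

    @property
    def n_classes(self) -> int:
        return self.s


@dataclasses.dataclass(frozen=True)
class CleavagePattern:
    """One labeled window: class 0 = no site, class k = site at interval k."""

    premirna_id: str
    window_start: int  # 1-based index a of the first nucleotide
    pattern_seq: str
    pattern_struct: str
    label: int


@dataclasses.dataclass
class PatternDataset:
    """Labeled patterns plus their parent-hairpin context."""

    config: PatternConfig
    samples: list[CleavagePattern]
    context: dict[str, tuple[str, str]]  # premirna_id -> (sequence, structure)
    variant: str = "custom"  # dataset1 | dataset2 | custom
    folds: np.ndarray | None = None  # per-sample fold id, or None

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.samples], dtype=np.int64)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.config.n_classes)

    def negative_fraction(self) -> float:
        """Share of class-0 (negative) patterns in the dataset."""
        return float((self.labels == 0).sum()) / len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.samples):
            seq, struct = self.context[p.premirna_id]
            rows.append({
                "pattern_id": f"{p.premirna_id}:{p.window_start}",
                "premirna_id": p.premirna_id,
                "window_start": p.window_start,
                "pattern_seq": p.pattern_seq,
                "pattern_struct": p.pattern_struct,
                "premirna_seq": seq,
                "premirna_struct": struct,
                "label": p.label,
                "fold": int(self.folds[i]) if self.folds is not None else None,
            })
        df = pd.DataFrame(rows)
        if self.folds is None:
            df = df.drop(columns=["fold"])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PatternDataset":
        if len(df) == 0:
            raise ValidationError("empty pattern dataset")
        s = len(df.iloc[0]["pattern_seq"])
        config = PatternConfig(s=s)
        samples = []
        context: dict[str, tuple[str, str]] = {}
        for row in df.itertuples(index=False):
            label = int(row.label)
            if not 0 <= label <= s - 1:
                raise ValidationError(
                    f"label {label} outside {{0..{s - 1}}} for pattern size {s}"
                )
            samples.append(CleavagePattern(
                premirna_id=row.premirna_id,
                window_start=int(row.window_start),
                pattern_seq=row.pattern_seq,
                pattern_struct=row.pattern_struct,
                label=label,
            ))
            context[row.premirna_id] = (row.premirna_seq, row.premirna_struct)
        folds = None
        if "fold" in df.columns:
            folds = df["fold"].to_numpy(dtype=np.int64)
        return cls(config=config, samples=samples, context=context, folds=folds)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PatternDataset):
            return NotImplemented
        same_folds = (
            (self.folds is None and other.folds is None)
            or (self.folds is not None and other.folds is not None
                and np.array_equal(self.folds, other.folds))
        )
        return (self.config == other.config and self.samples == other.samples
                and self.context == other.context and same_folds)


def infer_cleavage_sites(premirna: PreMiRNA,
                         annotations: list[MatureAnnotation]) -> list[CleavageSite]:
    """Infer the two Dicer cleavage intervals from the mature-arm coordinates."""
    mine = {a.arm: a for a in annotations if a.premirna_id == premirna.id}
    if set(mine) != {"5p", "3p"}:
        raise ValidationError(f"incomplete annotation: {premirna.id}")
    g5 = mine["5p"].end           # gap just 3' of the 5p mature's last nt
    g3 = mine["3p"].start - 1     # gap just 5' of the 3p mature's first nt
    L = premirna.length
    for g, arm in ((g5, "5p"), (g3, "3p")):
        if not 1 <= g <= L - 1:
            raise ValidationError(
                f"{premirna.id}: inferred {arm} site interval {g} outside [1, {L - 1}]"
            )
    if g5 >= g3:
        raise ValidationError(
            f"{premirna.id}: 5p site ({g5}) not upstream of 3p site ({g3}); "
            "mature arms overlap or coincide"
        )
    return [CleavageSite(g5, "5p"), CleavageSite(g3, "3p")]


def generate_patterns(premirna: PreMiRNA, config: PatternConfig) -> list[CleavagePattern]:
    """Generate all labeled windows; drop windows spanning two sites."""
    s = config.s
    L = premirna.length
    if L < s:
        raise ValidationError(f"{premirna.id}: length {L} < pattern size {s}")
    sites = sorted(site.interval for site in premirna.sites)
    patterns = []
    for a in range(1, L - s + 2):
        # window covers intervals a .. a+s-2
        inside = [g for g in sites if a <= g <= a + s - 2]
        if len(inside) > 1:
            continue
        label = inside[0] - a + 1 if inside else 0
        patterns.append(CleavagePattern(
            premirna_id=premirna.id,
            window_start=a,
            pattern_seq=premirna.sequence[a - 1:a + s - 1],
            pattern_struct=premirna.structure[a - 1:a + s - 1],
            label=label,
        ))
    return patterns


def _make_context(premirnas: list[PreMiRNA]) -> dict[str, tuple[str, str]]:
    return {p.id: (p.sequence, p.structure) for p in premirnas}


def _collect(premirnas: list[PreMiRNA], config: PatternConfig):
    positives, negatives = [], []
    for p in premirnas:
        for pat in generate_patterns(p, config):
            (positives if pat.label > 0 else negatives).append(pat)
    return positives, negatives


def build_dataset1(premirnas: list[PreMiRNA], config: PatternConfig,
                   n_neg: int = 20_000, seed: int = 0) -> PatternDataset:
    """All positive patterns plus ``n_neg`` uniformly sampled negatives."""
    positives, negatives = _collect(premirnas, config)
    rng = np.random.default_rng(seed)
    if len(negatives) < n_neg:
        warnings.warn(
            f"only {len(negatives)} negative patterns available, requested {n_neg}; "
            "keeping all", stacklevel=2)
        sampled = negatives
    else:
        idx = rng.choice(len(negatives), size=n_neg, replace=False)
        sampled = [negatives[i] for i in sorted(idx)]
    return PatternDataset(config=config, samples=positives + sampled,
                          context=_make_context(premirnas), variant="dataset1")


def build_dataset2(premirnas: list[PreMiRNA], config: PatternConfig,
                   neg_per_premirna: int = 2, seed: int = 0) -> PatternDataset:
    """All positives plus ``neg_per_premirna`` sampled negatives per hairpin."""
    rng = np.random.default_rng(seed)
    samples: list[CleavagePattern] = []
    for p in premirnas:
        patterns = generate_patterns(p, config)
        pos = [x for x in patterns if x.label > 0]
        neg = [x for x in patterns if x.label == 0]
        samples.extend(pos)
        if len(neg) < neg_per_premirna:
            warnings.warn(
                f"hairpin {p.id}: only {len(neg)} negative patterns, "
                f"requested {neg_per_premirna}; keeping all", stacklevel=2)
            samples.extend(neg)
        else:
            idx = rng.choice(len(neg), size=neg_per_premirna, replace=False)
            samples.extend(neg[i] for i in sorted(idx))
    return PatternDataset(config=config, samples=samples,
                          context=_make_context(premirnas), variant="dataset2")


def split_folds(dataset: PatternDataset, k: int = 5, seed: int = 0,
                group_by_premirna: bool = False) -> PatternDataset:
    """Assign k cross-validation folds, sizes differing by at most one.

    Default assignment is at the pattern level, so overlapping windows from
    one hairpin may land in different folds — a residual dependence accepted
    by the evaluation protocol.  ``group_by_premirna=True`` instead keeps
    all patterns of a hairpin in one fold (leakage-free alternative).
    """
    if k < 2:
        raise ValidationError(f"need at least 2 folds, got {k}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    folds = np.empty(n, dtype=np.int64)
    if group_by_premirna:
        ids = sorted({p.premirna_id for p in dataset.samples})
        perm = rng.permutation(len(ids))
        id_fold = {ids[j]: int(i % k) for i, j in enumerate(perm)}
        for i, p in enumerate(dataset.samples):
            folds[i] = id_fold[p.premirna_id]
    else:
        assignment = np.arange(n) % k  # sizes differ by <= 1
        folds[:] = assignment[rng.permutation(n)]
    return dataclasses.replace(dataset, folds=folds)


# -- redundancy reduction --------------------------------------------------

def _kmer_set(seq: str, k: int = 8) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _containment(a: set[str], b: set[str]) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def cluster_redundancy(records: list[SequenceRecord], threshold: float = 0.80,
                       cdhit_path: str | None = None,
                       k: int = 8) -> list[SequenceRecord]:
    """Reduce sequence redundancy; return one representative per cluster.

    If ``cdhit_path`` points at a cd-hit-est executable it is invoked and
    its representatives parsed.  Otherwise a built-in greedy clusterer is
    used: sequences are visited by descending length and joined to the
    first existing cluster whose representative shares a k-mer containment
    (|shared k-mers| / |k-mers of the shorter sequence|, k=8) at or above
    ``threshold``.  This fallback is a coarse identity estimate, not a
    replacement for alignment-based clustering; its use is logged.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValidationError(f"threshold must be in (0.5, 1.0], got {threshold}")
    if cdhit_path is not None:
        return _cluster_external(records, threshold, cdhit_path)
    logger.info("cluster_redundancy: using built-in greedy k-mer fallback "
                "(no cd-hit-est configured)")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SequenceRecord] = []
    rep_kmers: list[set[str]] = []
    for rec in order:
        km = _kmer_set(rec.sequence, k)
        if not any(_containment(km, rk) >= threshold for rk in rep_kmers):
            reps.append(rec)
            rep_kmers.append(km)
    original_order = {r.id: i for i, r in enumerate(records)}
    return sorted(reps, key=lambda r: original_order[r.id])


def _cluster_external(records: list[SequenceRecord], threshold: float,
                      cdhit_path: str) -> list[SequenceRecord]:
    if shutil.which(cdhit_path) is None:
        raise ValidationError(f"cd-hit-est executable not found: {cdhit_path}")
    from .io_formats import write_fasta
    with tempfile.TemporaryDirectory() as tmp:
        fa_in = Path(tmp) / "in.fasta"
        fa_out = Path(tmp) / "out.fasta"
        write_fasta(records, fa_in)
        proc = subprocess.run(
            [cdhit_path, "-i", str(fa_in), "-o", str(fa_out),
             "-c", str(threshold), "-n", "5"],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise ValidationError(f"cd-hit-est failed: {proc.stderr.strip()}")
        from .io_formats import read_fasta
        kept = {r.id for r in read_fasta(fa_out)}
    return [r for r in records if r.id in kept]


def assemble_premirnas(sequences: list[SequenceRecord],
                       structures: list[StructureRecord],
                       annotations: list[MatureAnnotation]) -> list[PreMiRNA]:
    """Join sequences, structures and annotations into annotated hairpins."""
    struct_by_id = {r.id: r.structure for r in structures}
    out = []
    for rec in sequences:
        if rec.id not in struct_by_id:
            raise ValidationError(f"no structure for hairpin {rec.id!r}")
        p = PreMiRNA(rec.id, rec.sequence, struct_by_id[rec.id])
        p.sites = infer_cleavage_sites(p, annotations)
        out.append(p)
    return out
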