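"""Seed-motif discovery across a mature miRNA catalogue.

miRNAs repress mRNAs through base pairing between the seed region at the 5'
end of the mature sequence and mRNA 3'UTRs.  Here the seed is defined as
nucleotides 1-8 of the mature miRNA (a deliberately inclusive definition; the
canonical 2-7/2-8 variants are available through ``seed_region``).  The module
answers three questions about a set of screen hits:

* which k-mers are shared between the hits' seeds (:func:`find_shared_motifs`),
* is a given motif over-represented among hits relative to the library
  background (:func:`motif_enrichment`, one-sided hypergeometric), and
* which catalogue members belong to the seed family of a motif
  (:func:`assign_seed_family`) — e.g. the AAGUGC "oncomotif" family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from scipy.stats import hypergeom

RNA_ALPHABET = frozenset("ACGU")

#: Default seed definition: 5' nucleotides 1-8 (1-based, inclusive).
DEFAULT_SEED_REGION = (1, 8)


def _normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and coerce the DNA alphabet (T) to RNA (U); validate."""
    s = str(seq).strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"illegal character(s) {sorted(bad)} in {context}: {s[:30]!r}"
        )
    if not s:
        raise ValueError(f"empty {context}")
    return s


@dataclass(frozen=True)
class MiRNARecord:
    mirna_id: str
    sequence: str
    locus: str | None = None


@dataclass
class MiRNACatalogue:
    """Mature miRNA sequences keyed by unique id, RNA alphabet."""

    records: list[MiRNARecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.mirna_id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate miRNA ids: {dupes}")
        normalized = []
        for r in self.records:
            seq = _normalize_sequence(r.sequence, context=f"sequence of {r.mirna_id}")
            if len(seq) < 8:
                raise ValueError(
                    f"sequence of {r.mirna_id} shorter than 8 nt ({len(seq)})"
                )
            normalized.append(MiRNARecord(r.mirna_id, seq, r.locus))
        self.records = normalized
        self._by_id = {r.mirna_id: r for r in self.records}

    @classmethod
    def from_fasta(cls, path) -> "MiRNACatalogue":
        """Read a mature-miRNA FASTA; id = first whitespace token of header."""
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(MiRNARecord(rec.id, str(rec.seq)))
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.mirna_id}\n{r.sequence}\n")

    @property
    def ids(self) -> list[str]:
        return [r.mirna_id for r in self.records]

    def sequence(self, mirna_id: str) -> str:
        return self._by_id[mirna_id].sequence

    def seed(self, mirna_id: str, seed_region=DEFAULT_SEED_REGION) -> str:
        return extract_seed(self.sequence(mirna_id), seed_region=seed_region)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self._by_id


@dataclass(frozen=True)
class SeedFamily:
    """miRNAs whose seed contains ``motif``; offsets are 0-based within the seed."""

    motif: str
    member_ids: tuple[str, ...]
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.member_ids) != len(self.offsets):
            raise ValueError("member_ids and offsets length mismatch")

    def __len__(self) -> int:
        return len(self.member_ids)


def extract_seed(sequence: str, seed_region=DEFAULT_SEED_REGION) -> str:
    """Extract the seed (default nt 1-8) of a mature miRNA sequence.

    The sequence is case-normalized and coerced to the RNA alphabet first.
    Raises ``ValueError`` on sequences shorter than the seed region or on
    characters outside ACGU(T).
    """
    start, end = seed_region
    if not (1 <= start <= end):
        raise ValueError(f"invalid seed region {seed_region}")
    seq = _normalize_sequence(sequence)
    if len(seq) < end:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than seed region end {end}"
        )
    return seq[start - 1 : end]


def _check_motif(motif: str, seed_len: int) -> str:
    motif = _normalize_sequence(motif, context="motif")
    if len(motif) > seed_len:
        raise ValueError(
            f"motif {motif!r} longer than the {seed_len}-nt seed region"
        )
    return motif


def find_shared_motifs(
    hit_ids,
    catalogue: MiRNACatalogue,
    k: int = 6,
    seed_region=DEFAULT_SEED_REGION,
) -> pd.DataFrame:
    """Enumerate k-mers within hit seeds and count them in hits vs background.

    Returns a DataFrame (motif, hit_count, background_count) sorted by
    hit_count descending, then lexicographically — the top row is the most
    widely shared seed motif among the hits.
    """
    seed_len = seed_region[1] - seed_region[0] + 1
    if not 1 <= k <= seed_len:
        raise ValueError(f"k={k} outside 1..{seed_len}")
    hit_ids = sorted(set(hit_ids))
    if not hit_ids:
        raise ValueError("empty hit set")
    missing = [h for h in hit_ids if h not in catalogue]
    if missing:
        raise KeyError(f"hit ids not in catalogue: {missing}")

    def kmers(seed: str) -> set[str]:
        return {seed[i : i + k] for i in range(len(seed) - k + 1)}

    hit_counts: Counter = Counter()
    for h in hit_ids:
        hit_counts.update(kmers(catalogue.seed(h, seed_region)))
    bg_counts: Counter = Counter()
    for mid in catalogue.ids:
        seen = kmers(catalogue.seed(mid, seed_region))
        bg_counts.update(seen & set(hit_counts))

    rows = sorted(
        ((m, hit_counts[m], bg_counts[m]) for m in hit_counts),
        key=lambda t: (-t[1], t[0]),
    )
    return pd.DataFrame(rows, columns=["motif", "hit_count", "background_count"])


def motif_enrichment(
    motif: str,
    hit_ids,
    catalogue: MiRNACatalogue,
    seed_region=DEFAULT_SEED_REGION,
) -> float:
    """One-sided hypergeometric p-value for motif over-representation in hits.

    P(X >= x) with X ~ Hypergeom(N=catalogue size, K=seeds containing motif,
    n=|hits|) and x = number of hit seeds containing the motif.  Quantifies
    the qualitative shared-seed observation; p=1 when no hit carries it.
    """
    seed_len = seed_region[1] - seed_region[0] + 1
    motif = _check_motif(motif, seed_len)
    hit_ids = sorted(set(hit_ids))
    missing = [h for h in hit_ids if h not in catalogue]
    if missing:
        raise KeyError(f"hit ids not in catalogue: {missing}")
    carriers = {
        mid for mid in catalogue.ids if motif in catalogue.seed(mid, seed_region)
    }
    N = len(catalogue)
    K = len(carriers)
    n = len(hit_ids)
    x = sum(1 for h in hit_ids if h in carriers)
    # survival function at x-1 gives P(X >= x)
    return float(hypergeom.sf(x - 1, N, K, n))


def assign_seed_family(
    catalogue: MiRNACatalogue,
    motif: str,
    seed_region=DEFAULT_SEED_REGION,
) -> SeedFamily:
    """All catalogue members whose seed contains ``motif``, with first offsets."""
    seed_len = seed_region[1] - seed_region[0] + 1
    motif = _check_motif(motif, seed_len)
    members, offsets = [], []
    for mid in sorted(catalogue.ids):
        seed = catalogue.seed(mid, seed_region)
        off = seed.find(motif)
        if off >= 0:
            members.append(mid)
            offsets.append(off)
    return SeedFamily(motif=motif, member_ids=tuple(members), offsets=tuple(offsets))


def family_to_frame(family: SeedFamily) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": family.member_ids,
            "motif": family.motif,
            "offset": family.offsets,
        }
    )
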