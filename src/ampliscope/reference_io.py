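"""Reference 16S sequences with taxonomy, and identity-threshold refinement.

Reads a reference set as FASTA plus a two-column (ID, lineage) tab-separated
taxonomy table, understanding both the SILVA ``D_0__Bacteria;D_1__...`` and the
Greengenes ``k__Bacteria;p__...`` lineage dialects. Refinement collapses the
set at an identity threshold (the conventional 99% for near-full-length 16S)
by greedy centroid clustering, mirroring common reference-dereplication
practice.

Identity definition (this changes cluster counts, so it is stated precisely):
matching columns divided by alignment length of a global alignment with free
end gaps, where alignment length counts the columns between the first and last
column in which *both* sequences have a residue — terminal overhangs are free,
internal gaps count against identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .errors import DataError
from .primer_core import IUPAC_SETS

logger = logging.getLogger(__name__)

#: Fixed rank order, domain/kingdom down to genus.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Greengenes-style single-letter prefixes.
_GG_PREFIXES = {"k": "domain", "d": "domain", "p": "phylum", "c": "class",
                "o": "order", "f": "family", "g": "genus"}


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ranked lineage from domain/kingdom to genus; missing ranks are empty strings."""

    ranks: tuple[tuple[str, str], ...]
    raw: str = ""

    def get(self, rank: str) -> str:
        for name, value in self.ranks:
            if name == rank:
                return value
        raise KeyError(f"unknown rank {rank!r}; known ranks: {RANKS}")

    @property
    def is_empty(self) -> bool:
        return all(v == "" for _, v in self.ranks)


EMPTY_LINEAGE = TaxonomyLineage(ranks=tuple((r, "") for r in RANKS), raw="")


def parse_lineage(raw: str) -> TaxonomyLineage:
    """Parse a semicolon-delimited lineage string into ranked taxa.

    Strips ``D_0__`` (SILVA) and ``k__``/``p__``/... (Greengenes) prefixes.
    Prefixed tokens land at their named rank; unprefixed tokens are assigned
    positionally. Unparseable tokens are retained verbatim at their position
    with a warning — never dropped. Tokens below genus are ignored.
    """
    values = {r: "" for r in RANKS}
    tokens = [t.strip() for t in raw.split(";")] if raw.strip() else []
    for pos, tok in enumerate(tokens):
        if tok == "":
            continue
        rank = None
        name = tok
        if len(tok) >= 3 and tok[1:3] == "__" and tok[0].lower() in _GG_PREFIXES:
            rank = _GG_PREFIXES[tok[0].lower()]
            name = tok[3:].strip()
        elif tok[:2].upper() == "D_" and "__" in tok:
            idx_str, _, rest = tok[2:].partition("__")
            try:
                idx = int(idx_str)
            except ValueError:
                idx = -1
            if 0 <= idx < len(RANKS):
                rank = RANKS[idx]
                name = rest.strip()
        if rank is None:
            if pos < len(RANKS):
                rank = RANKS[pos]
            else:
                continue  # token below genus
            if name and not name.replace(" ", "").replace("-", "").replace("_", "").isalnum():
                logger.warning("lineage token %r retained verbatim at rank %s", tok, rank)
        if values[rank]:
            logger.warning("lineage %r: rank %s assigned twice; keeping first", raw, rank)
        else:
            values[rank] = name
    return TaxonomyLineage(ranks=tuple((r, values[r]) for r in RANKS), raw=raw)


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference 16S sequence with its taxonomy lineage."""

    id: str
    sequence: str
    lineage: TaxonomyLineage = EMPTY_LINEAGE

    def __len__(self) -> int:
        return len(self.sequence)


def ambiguity_fraction(seq: str) -> float:
    """Fraction of positions that are not concrete A/C/G/T."""
    if not seq:
        return 0.0
    return sum(1 for c in seq.upper() if c not in "ACGT") / len(seq)


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLineage]:
    """Read a two-column (ID, lineage) TSV into parsed lineages."""
    out: dict[str, TaxonomyLineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path} line {lineno}: expected 2 tab-separated "
                                f"columns (id, lineage)")
            out[parts[0].strip()] = parse_lineage(parts[1])
    return out


def read_references(fasta: str | Path, taxonomy: str | Path | None = None,
                    min_length: int = 500,
                    max_ambiguous_frac: float = 0.05) -> list[ReferenceRecord]:
    """Read FASTA + taxonomy into joined reference records.

    IDs present in the FASTA but absent from the taxonomy get an all-empty
    lineage (with a warning). Duplicate FASTA IDs or an empty FASTA are
    errors. Quality guards (both configurable; disable with 0): sequences
    shorter than ``min_length`` or with more than ``max_ambiguous_frac``
    ambiguity codes are excluded with a logged count.
    """
    lineages = read_taxonomy(taxonomy) if taxonomy is not None else {}
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    n_short = n_ambig = n_nolineage = 0
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate FASTA ID {rec.id!r} in {fasta}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if min_length and len(seq) < min_length:
            n_short += 1
            continue
        if max_ambiguous_frac and ambiguity_fraction(seq) > max_ambiguous_frac:
            n_ambig += 1
            continue
        lin = lineages.get(rec.id)
        if lin is None:
            n_nolineage += 1
            lin = EMPTY_LINEAGE
        records.append(ReferenceRecord(id=rec.id, sequence=seq, lineage=lin))
    if not seen:
        raise DataError(f"empty FASTA: {fasta}")
    if n_short:
        logger.warning("excluded %d sequence(s) shorter than %d bp", n_short, min_length)
    if n_ambig:
        logger.warning("excluded %d sequence(s) with >%.0f%% ambiguity codes",
                       n_ambig, 100 * max_ambiguous_frac)
    if n_nolineage:
        logger.warning("%d record(s) had no taxonomy entry; lineage left empty",
                       n_nolineage)
    return records


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_taxonomy(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.lineage.raw}\n")


# ---------------------------------------------------------------------------
# Refinement (greedy centroid clustering at an identity threshold)
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Partition of record IDs into centroid-led clusters at one threshold."""

    clusters: list[tuple[str, list[str]]]
    threshold: float
    identities: dict[str, float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> list[str]:
        return [m for _, members in self.clusters for m in members]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("centroid_id\tmember_id\tidentity\n")
            for centroid, members in self.clusters:
                for m in members:
                    ident = 1.0 if m == centroid else self.identities.get(m, float("nan"))
                    fh.write(f"{centroid}\t{m}\t{ident:.6f}\n")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    # free end gaps (attribute names changed across Biopython versions)
    new_names = ("open_end_insertion_score", "extend_end_insertion_score",
                 "open_end_deletion_score", "extend_end_deletion_score")
    old_names = ("target_end_open_gap_score", "target_end_extend_gap_score",
                 "query_end_open_gap_score", "query_end_extend_gap_score")
    try:
        for name in new_names:
            setattr(aligner, name, 0)
    except AttributeError:
        for name in old_names:
            setattr(aligner, name, 0)
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Identity of the best global alignment of ``a`` and ``b`` with free end gaps.

    matches / alignment length, where alignment length spans the columns
    between the first and last column in which both sequences carry a residue
    (terminal overhangs free; internal gaps count against identity).
    """
    if a == b:
        return 1.0
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    # trim terminal columns where either row is a gap
    start = 0
    while start < len(ga) and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = len(ga)
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    cols = end - start
    matches = sum(1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-")
    return matches / cols


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def refine_references(records: Sequence[ReferenceRecord], threshold: float = 0.99,
                      prefilter_above: int = 50_000
                      ) -> tuple[ClusterSet, list[ReferenceRecord]]:
    """Greedy centroid clustering at an identity threshold.

    Records are visited sorted by length descending (ties by id ascending);
    each joins the first existing centroid with identity >= threshold, else
    founds a new cluster. The sort order is part of the contract — it makes
    the partition reproducible.

    Above ``prefilter_above`` input records, a shared-8-mer prefilter skips
    alignment against centroids sharing no 8-mer with the query (at thresholds
    >= 0.9 such a pair cannot reach the threshold, so the result is unchanged).
    Returns the cluster set and the centroid-only record collection.
    """
    if not records:
        raise DataError("refine_references: no input records")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    ids = [r.id for r in order]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate record IDs in refine_references input")

    use_prefilter = len(records) > prefilter_above and threshold >= 0.9
    aligner = _make_aligner()
    centroids: list[ReferenceRecord] = []
    centroid_kmers: list[set[str]] = []
    clusters: list[list[str]] = []
    identities: dict[str, float] = {}

    for rec in order:
        kmers = _kmer_set(rec.sequence) if use_prefilter else None
        assigned = False
        for ci, cent in enumerate(centroids):
            if use_prefilter and not (kmers & centroid_kmers[ci]):
                continue
            ident = pairwise_identity(cent.sequence, rec.sequence, aligner)
            if ident >= threshold:
                clusters[ci].append(rec.id)
                identities[rec.id] = ident
                assigned = True
                break
        if not assigned:
            centroids.append(rec)
            if use_prefilter:
                centroid_kmers.append(_kmer_set(rec.sequence))
            clusters.append([rec.id])
    cluster_set = ClusterSet(
        clusters=[(c.id, members) for c, members in zip(centroids, clusters)],
        threshold=threshold,
        identities=identities,
    )
    return cluster_set, centroids
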