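"""Binding-site sequence-variant profiling and primer-pool optimization.

Given a taxonomically labeled reference set and one primer, this module
extracts the best binding window from every reference, tallies the distinct
site sequences observed, annotates each variant with its distance to the
best-matching primer formulation and the taxa it dominates in, and renders the
classic variant-table view (dots for positions identical to the most common
variant, so that lineage-specific mispairings — e.g. the Bifidobacteriales
27F-site substitutions — stand out).

Pool optimization is greedy weighted set cover over observed occurrence mass:
starting from the original primer, repeatedly add the candidate covering the
most currently-uncovered occurrences exactly (0 mismatches), until full
coverage or the pool size limit. Candidates are observed variant strings
verbatim; optionally, conservative IUPAC merges of a variant with an existing
pool member are allowed when every expansion the merge adds matches an
observed site — extra degeneracy must never introduce formulations matching
nothing that was observed, since unobserved expansions only inflate
mispriming risk.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DataError
from .primer_core import (
    DegeneratePrimer,
    degeneracy,
    expand,
    merge_codes,
    mismatches,
)
from .insilico_amplification import best_expansion_for, find_binding_sites
from .reference_io import RANKS, ReferenceRecord, TaxonomyLineage

logger = logging.getLogger(__name__)

DEFAULT_EXTRACTION_CEILING = 5
DEFAULT_RANK = "order"
DOMINANCE_SHARE = 0.5


@dataclass(frozen=True)
class SiteExtraction:
    record_id: str
    site_sequence: str
    mismatch_count: int


@dataclass
class ExtractionResult:
    primer_name: str
    extractions: list[SiteExtraction]
    missed_ids: list[str]

    @property
    def n_missed(self) -> int:
        return len(self.missed_ids)


def extract_sites(records: Sequence[ReferenceRecord], primer: DegeneratePrimer,
                  ceiling: int = DEFAULT_EXTRACTION_CEILING) -> ExtractionResult:
    """Best binding window per record, oriented 5'->3' in primer orientation.

    The best window is the one with the fewest mismatches (leftmost on ties),
    searched with a generous mismatch ceiling so that heavily mispaired sites
    are still profiled. Records with no window within the ceiling are tallied
    as misses, never fatal.
    """
    if not records:
        raise DataError("extract_sites: no input records")
    extractions: list[SiteExtraction] = []
    missed: list[str] = []
    for rec in records:
        hits = find_binding_sites(rec, primer, max_mismatches=ceiling)
        if hits:
            best = hits[0]  # already sorted (mismatch asc, start asc)
            extractions.append(SiteExtraction(
                record_id=rec.id, site_sequence=best.site_sequence,
                mismatch_count=best.mismatch_count,
            ))
        else:
            missed.append(rec.id)
    if missed:
        logger.info("primer %s: site not found within %d mismatches for %d "
                    "record(s)", primer.name, ceiling, len(missed))
    return ExtractionResult(primer_name=primer.name, extractions=extractions,
                            missed_ids=missed)


@dataclass(frozen=True)
class VariantRow:
    variant_sequence: str
    occurrence_count: int
    per_taxon: tuple[tuple[str, int], ...]  # sorted by count desc, name asc
    min_mismatch_count: int
    best_expansion: str
    dominant_groups: tuple[str, ...]


@dataclass
class SiteVariantTable:
    """Per-primer tally of observed binding-site sequences.

    Rows are sorted by occurrence count descending (ties lexicographic by
    variant). ``consensus`` is the most common variant; the dot-rendered view
    marks positions deviating from it.
    """

    primer_name: str
    rank: str
    rows: list[VariantRow]
    n_missed: int = 0

    @property
    def total_occurrences(self) -> int:
        return sum(r.occurrence_count for r in self.rows)

    @property
    def consensus(self) -> str:
        return self.rows[0].variant_sequence

    def render(self) -> str:
        """Text view: dots where a variant matches the most common one."""
        top = self.consensus
        lines = [f"# primer {self.primer_name}, grouped at rank {self.rank}",
                 f"{'occurrences':>11}  {'mm':>2}  site ({len(top)} nt)  dominant group(s)"]
        for row in self.rows:
            shown = "".join(
                "." if a == b else a
                for a, b in zip(row.variant_sequence, top)
            )
            lines.append(f"{row.occurrence_count:>11}  {row.min_mismatch_count:>2}  "
                         f"{shown}  {', '.join(row.dominant_groups)}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant_sequence\toccurrence_count\tmin_mismatch_count\t"
                     "best_expansion\tdominant_groups\tper_taxon\n")
            for r in self.rows:
                taxa = ",".join(f"{t}:{c}" for t, c in r.per_taxon)
                fh.write(f"{r.variant_sequence}\t{r.occurrence_count}\t"
                         f"{r.min_mismatch_count}\t{r.best_expansion}\t"
                         f"{';'.join(r.dominant_groups)}\t{taxa}\n")


def _group_label(lineage: TaxonomyLineage, rank: str) -> str:
    """Taxon label at ``rank``; empty values fall back to 'unassigned'.

    Lineage tokens that carry no recognizable prefix are kept verbatim at
    their position by the parser, so groups named below class without an
    order token (e.g. Mollicutes RF39) surface under their positional slot.
    """
    value = lineage.get(rank)
    return value if value else "unassigned"


def tally_variants(extractions: Iterable[SiteExtraction],
                   lineages: Mapping[str, TaxonomyLineage],
                   primer: DegeneratePrimer,
                   rank: str = DEFAULT_RANK) -> SiteVariantTable:
    """Group identical site strings and annotate mismatches and dominant taxa.

    Per variant: total occurrence count, per-taxon counts at the chosen rank,
    minimum mismatch count against the (degenerate) primer, the best-matching
    concrete expansion, and the dominant group(s) — the taxon holding the
    plurality of the variant's occurrences (reported singly when its share is
    >= 0.5, otherwise the top two are listed).
    """
    if rank not in RANKS:
        raise DataError(f"rank {rank!r} not in lineage schema {RANKS}")
    extractions = list(extractions)
    if not extractions:
        raise DataError("tally_variants: no extractions")

    by_variant: dict[str, Counter] = {}
    for ex in extractions:
        lineage = lineages.get(ex.record_id)
        group = _group_label(lineage, rank) if lineage is not None else "unassigned"
        by_variant.setdefault(ex.site_sequence, Counter())[group] += 1

    rows: list[VariantRow] = []
    for variant, taxa in by_variant.items():
        best_exp, mm = best_expansion_for(primer, variant)
        total = sum(taxa.values())
        ranked = sorted(taxa.items(), key=lambda kv: (-kv[1], kv[0]))
        top_taxon, top_count = ranked[0]
        if top_count / total >= DOMINANCE_SHARE:
            dominant = (top_taxon,)
        else:
            dominant = tuple(t for t, _ in ranked[:2])
        rows.append(VariantRow(
            variant_sequence=variant, occurrence_count=total,
            per_taxon=tuple(ranked), min_mismatch_count=mm,
            best_expansion=best_exp, dominant_groups=dominant,
        ))
    rows.sort(key=lambda r: (-r.occurrence_count, r.variant_sequence))
    return SiteVariantTable(primer_name=primer.name, rank=rank, rows=rows)


# ---------------------------------------------------------------------------
# Primer-pool optimization (greedy weighted set cover)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolStep:
    added: str
    newly_covered: int
    exact_coverage: float


@dataclass
class PoolProposal:
    """A proposed primer pool with its exact-match coverage of observed sites."""

    primer_name: str
    pool: list[str]  # IUPAC sequences, original primer first
    exact_coverage: float
    residual: int  # worst remaining min-mismatch count (0 at full coverage)
    steps: list[PoolStep] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("member\tsequence\tdegeneracy\n")
            for i, seq in enumerate(self.pool):
                label = self.primer_name if i == 0 else f"{self.primer_name}-pool{i}"
                fh.write(f"{label}\t{seq}\t{degeneracy(seq)}\n")

    def to_primer_file(self, path: str | Path, direction: str,
                       region: str = "") -> None:
        """Write the pool in the loadable primer-table format."""
        with open(path, "w") as fh:
            fh.write("name\tdirection\tsequence\tregion\n")
            for i, seq in enumerate(self.pool):
                label = self.primer_name if i == 0 else f"{self.primer_name}-pool{i}"
                fh.write(f"{label}\t{direction}\t{seq}\t{region}\n")


def _covers(member: str, variant: str) -> bool:
    return mismatches(member, variant) == 0


def _coverage_mass(pool: Sequence[str], weights: Mapping[str, int]) -> int:
    return sum(w for v, w in weights.items() if any(_covers(m, v) for m in pool))


def optimize_pool(table: SiteVariantTable, primer: DegeneratePrimer,
                  max_pool_size: int = 4,
                  allow_degenerate: bool = False,
                  degeneracy_cap: int = 64) -> PoolProposal:
    """Greedy weighted set cover of observed site occurrences.

    Starts from the original primer. Each step adds the candidate that covers
    the most currently-uncovered occurrence mass at 0 mismatches; ties prefer
    lower degeneracy, then lexicographic order. Candidates are uncovered
    variant strings verbatim; with ``allow_degenerate``, also the IUPAC merge
    of such a variant with an existing pool member, admitted only when every
    expansion of the merge matches an observed variant or is an expansion of
    the original primer (degeneracy must never buy coverage of sites nobody
    observed). A merge with a non-original member replaces that member; the
    original primer is never removed. Stops at full coverage, zero gain, or
    the size limit.
    """
    if max_pool_size < 1:
        raise DataError("max_pool_size must be >= 1")
    if not table.rows:
        raise DataError("optimize_pool: empty variant table")

    weights = {r.variant_sequence: r.occurrence_count for r in table.rows}
    total = sum(weights.values())
    observed = set(weights)
    primer_expansions = set(expand(primer.sequence))
    admissible = observed | primer_expansions

    pool: list[str] = [primer.sequence]
    covered_mass = _coverage_mass(pool, weights)
    steps: list[PoolStep] = [PoolStep(primer.sequence, covered_mass,
                                      covered_mass / total)]

    def uncovered() -> dict[str, int]:
        return {v: w for v, w in weights.items()
                if not any(_covers(m, v) for m in pool)}

    while len(pool) < max_pool_size:
        remaining = uncovered()
        if not remaining:
            break
        # candidate -> (gain, replaces_index or None)
        candidates: dict[str, tuple[int, int | None]] = {}
        for v in remaining:
            gain = sum(w for u, w in remaining.items() if _covers(v, u))
            candidates[v] = (gain, None)
        if allow_degenerate:
            for v in remaining:
                for mi, member in enumerate(pool):
                    if len(member) != len(v):
                        continue
                    merged = merge_codes(member, v)
                    if degeneracy(merged) > degeneracy_cap:
                        continue
                    if any(e not in admissible for e in expand(merged)):
                        continue
                    gain = sum(w for u, w in remaining.items() if _covers(merged, u))
                    prev = candidates.get(merged)
                    repl = None if mi == 0 else mi
                    if prev is None or gain > prev[0]:
                        candidates[merged] = (gain, repl)
        best_seq, (best_gain, replaces) = min(
            candidates.items(),
            key=lambda kv: (-kv[1][0], degeneracy(kv[0]), kv[0]),
        )
        if best_gain <= 0:
            break
        if replaces is not None:
            pool[replaces] = best_seq
        else:
            pool.append(best_seq)
        covered_mass = _coverage_mass(pool, weights)
        steps.append(PoolStep(best_seq, best_gain, covered_mass / total))

    remaining = uncovered()
    residual = max(
        (min(mismatches(m, v) for m in pool) for v in remaining), default=0
    )
    return PoolProposal(
        primer_name=primer.name, pool=pool,
        exact_coverage=covered_mass / total, residual=residual, steps=steps,
    )
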