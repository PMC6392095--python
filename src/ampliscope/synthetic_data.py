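"""Deterministic synthetic reference sets with planted primer-binding sites.

Real 16S reference snapshots are large, versioned downloads; every analysis in
this package is instead testable against generated references whose ground
truth is known by construction. A *layout template* is a random-background
sequence with one concrete expansion of each primer written at its declared
footprint — by default the E. coli-numbering footprints of the study primers
(27F-YM at 8-27, 338R at 338-356, 341F at 341-357, 515F at 515-532, 806RB at
787-806; 1-based inclusive). The background is rejection-sampled so that no
off-target window lies within 2 mismatches of any planted primer, making site
search unambiguous.

A *reference set* is built per taxon from such templates, with binding-site
variants planted into exactly ``round(frequency * n)`` records chosen by a
seeded draw. The generator emits standard FASTA + taxonomy TSV plus a manifest
recording every planted site string and its true count — the recovery oracle
for the variant-tallying analysis.

Randomness comes from numpy's PCG64 via ``numpy.random.default_rng``; a single
integer seed makes all outputs byte-identical across runs. Per-record streams
are derived with ``SeedSequence.spawn`` so record order never couples streams.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError
from .primer_core import (
    IUPAC_SETS,
    DegeneratePrimer,
    PrimerPair,
    expand,
    revcomp,
    validate_iupac,
)
from .reference_io import ReferenceRecord, parse_lineage, write_fasta, write_taxonomy

#: E. coli-numbering footprints of the study primers, 1-based inclusive.
ECOLI_FOOTPRINTS: dict[str, tuple[int, int]] = {
    "27F-YM": (8, 27),
    "338R": (338, 356),
    "341F": (341, 357),
    "515F": (515, 532),
    "806RB": (787, 806),
}

DEFAULT_TEMPLATE_LENGTH = 1600
#: background windows closer than this (mismatches) to any primer are rejected
OFFTARGET_MIN_MISMATCHES = 3

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class LayoutTemplate:
    """A synthetic template with declared primer footprints.

    ``footprints`` maps primer name to 0-based half-open plus-strand
    coordinates; ``planted`` maps primer name to the concrete sequence written
    there in primer orientation (5'->3' along the primer).
    """

    sequence: str
    footprints: dict[str, tuple[int, int]]
    planted: dict[str, str]
    seed: int | None = None

    def footprint_1based(self, primer_name: str) -> tuple[int, int]:
        s, e = self.footprints[primer_name]
        return s + 1, e


def _primers_of(pair_or_primers) -> list[DegeneratePrimer]:
    if isinstance(pair_or_primers, PrimerPair):
        return [pair_or_primers.forward, pair_or_primers.reverse]
    if isinstance(pair_or_primers, DegeneratePrimer):
        return [pair_or_primers]
    return list(pair_or_primers)


def _offtarget_clean(template: np.ndarray, queries: list[np.ndarray],
                     allowed: list[set[int]]) -> bool:
    """True when no window outside the allowed starts is within 2 mismatches."""
    from .insilico_amplification import _window_mismatch_counts

    for q_mask, ok_starts in zip(queries, allowed):
        counts = _window_mismatch_counts(template, q_mask)
        close = np.flatnonzero(counts < OFFTARGET_MIN_MISMATCHES)
        if any(int(s) not in ok_starts for s in close):
            return False
    return True


def build_layout_template(pair_or_primers, total_length: int = DEFAULT_TEMPLATE_LENGTH,
                          footprints: Mapping[str, tuple[int, int]] | None = None,
                          seed: int | None = 0,
                          base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                          rng: np.random.Generator | None = None,
                          planted_override: Mapping[str, str] | None = None,
                          max_attempts: int = 50) -> LayoutTemplate:
    """Build a random-background template with planted primer footprints.

    ``footprints`` gives 1-based inclusive intervals per primer name
    (defaults to the E. coli-numbering table for known primer names).
    Footprints may overlap — on the real gene 338R (338-356) and 341F
    (341-357) do — in which case the planted bases must satisfy both primers:
    overlapping degenerate constraints are intersected position-wise and one
    concrete base is drawn per position (an empty intersection is an
    impossible layout). The forward primer is written along the plus strand,
    the reverse primer as its reverse complement. The background is re-drawn
    until no off-target window lies within 2 mismatches of any primer.

    ``planted_override`` fixes the site written for a primer (a concrete
    sequence in primer orientation, e.g. a deliberate variant). Overrides are
    applied after the degenerate constraints and in mapping order, each
    winning position-wise — a variant planted at one primer's site is thereby
    also visible through any overlapping primer's footprint, exactly as a real
    substitution would be. ``LayoutTemplate.planted`` always reports the
    realized site of every primer.
    """
    primers = _primers_of(pair_or_primers)
    if rng is None:
        rng = np.random.default_rng(seed)

    resolved: dict[str, tuple[int, int]] = {}
    for p in primers:
        if footprints is not None and p.name in footprints:
            s1, e1 = footprints[p.name]
        elif p.name in ECOLI_FOOTPRINTS:
            s1, e1 = ECOLI_FOOTPRINTS[p.name]
        else:
            raise DataError(f"no footprint given for primer {p.name!r}")
        start, end = s1 - 1, e1  # to 0-based half-open
        if end - start != len(p):
            raise DataError(
                f"footprint {s1}-{e1} spans {end - start} bp but primer "
                f"{p.name} is {len(p)} bp"
            )
        if start < 0 or end > total_length:
            raise DataError(f"footprint {s1}-{e1} of {p.name} outside template "
                            f"of length {total_length}")
        resolved[p.name] = (start, end)

    by_name = {p.name: p for p in primers}

    # position-wise constraints on the plus strand from degenerate primers
    constraints: dict[int, frozenset[str]] = {}
    for p in primers:
        start, end = resolved[p.name]
        plus = p.plus_strand_query()
        for j, code in enumerate(plus):
            want = IUPAC_SETS[code]
            have = constraints.get(start + j)
            merged = want if have is None else (have & want)
            if not merged:
                raise DataError(
                    f"impossible layout: overlapping footprints impose "
                    f"contradictory bases at template position {start + j}"
                )
            constraints[start + j] = merged

    # draw one concrete base per constrained position (a consistent joint
    # expansion of all primers), then apply overrides, later ones winning
    fixed: dict[int, str] = {
        pos: sorted(allowed_bases)[int(rng.integers(len(allowed_bases)))]
        for pos, allowed_bases in sorted(constraints.items())
    }
    if planted_override:
        for name, site in planted_override.items():
            if name not in resolved:
                raise DataError(f"override for unknown primer {name!r}")
            site = validate_iupac(site)
            p = by_name[name]
            if len(site) != len(p):
                raise DataError(f"planted override for {name} has length "
                                f"{len(site)}, primer is {len(p)} bp")
            plus = site if p.direction == "forward" else revcomp(site)
            start, _ = resolved[name]
            for j, base in enumerate(plus):
                fixed[start + j] = base

    from .insilico_amplification import _encode

    q_masks = [_encode(p.plus_strand_query()) for p in primers]
    # every footprint start is exempt from the off-target check: a planted
    # variant site may legitimately sit close to (or far from) its own primer
    all_starts = {s for s, _ in resolved.values()}
    allowed = [set(all_starts) for _ in primers]
    probs = np.asarray(base_freqs, dtype=float)
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("base_freqs must be 4 probabilities summing to 1")

    fixed_pos = np.fromiter(fixed.keys(), dtype=int)
    fixed_bases = np.array([b.encode() for b in fixed.values()], dtype="S1")

    for _ in range(max_attempts):
        arr = rng.choice(_BASES, size=total_length, p=probs)
        arr[fixed_pos] = fixed_bases
        template = arr.tobytes().decode()
        t_mask = _encode(template)
        if _offtarget_clean(t_mask, q_masks, allowed):
            planted = {}
            for p in primers:
                s, e = resolved[p.name]
                window = template[s:e]
                planted[p.name] = window if p.direction == "forward" else revcomp(window)
            return LayoutTemplate(sequence=template, footprints=resolved,
                                  planted=planted, seed=seed)
    raise DataError(
        f"could not build an off-target-free layout in {max_attempts} attempts; "
        f"layout may be impossible (template too short or footprints adjacent "
        f"to primer-like background)"
    )


# ---------------------------------------------------------------------------
# Reference-set generation with planted variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedVariant:
    """A binding-site variant planted into a fraction of one taxon's records.

    ``substitutions`` are (0-based position within the site, new base) applied
    to the canonical planted site, in primer orientation; alternatively give
    the full ``site_sequence``. ``frequency`` is the fraction of the taxon's
    records carrying the variant (applied to exactly ``round(f * n)`` records).
    """

    taxon: str
    primer_name: str
    frequency: float
    substitutions: tuple[tuple[int, str], ...] = ()
    site_sequence: str | None = None

    def __post_init__(self):
        if not 0 <= self.frequency <= 1:
            raise DataError(f"variant frequency {self.frequency} outside [0, 1]")
        if self.site_sequence is None and not self.substitutions:
            raise DataError("variant needs substitutions or a full site_sequence")

    def realize(self, canonical_site: str) -> str:
        if self.site_sequence is not None:
            site = validate_iupac(self.site_sequence)
            if len(site) != len(canonical_site):
                raise DataError(
                    f"variant site length {len(site)} != primer length "
                    f"{len(canonical_site)}"
                )
            return site
        site = list(canonical_site)
        for pos, base in self.substitutions:
            if not 0 <= pos < len(site):
                raise DataError(f"substitution position {pos} outside site")
            site[pos] = validate_iupac(base)
        return "".join(site)


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    lineage: str  # semicolon-delimited, any supported dialect
    n_records: int


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for a synthetic reference set; identical spec+seed =>
    byte-identical output."""

    taxa: tuple[TaxonSpec, ...]
    primers: tuple[DegeneratePrimer, ...]
    seed: int = 0
    total_length: int = DEFAULT_TEMPLATE_LENGTH
    footprints: Mapping[str, tuple[int, int]] | None = None
    variants: tuple[PlantedVariant, ...] = ()
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        names = {p.name for p in self.primers}
        for v in self.variants:
            if v.primer_name not in names:
                raise DataError(f"variant references unknown primer {v.primer_name!r}")
            if v.taxon not in {t.name for t in self.taxa}:
                raise DataError(f"variant references unknown taxon {v.taxon!r}")


@dataclass
class GroundTruthManifest:
    """Planted site strings and their true counts, per (taxon, primer)."""

    rows: list[dict]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\tprimer\tsite_sequence\tcount\tkind\n")
            for r in self.rows:
                fh.write(f"{r['taxon']}\t{r['primer']}\t{r['site_sequence']}\t"
                         f"{r['count']}\t{r['kind']}\n")

    def count_for(self, taxon: str, primer: str, site: str) -> int:
        for r in self.rows:
            if (r["taxon"], r["primer"], r["site_sequence"]) == (taxon, primer, site):
                return r["count"]
        return 0


def generate_reference_set(spec: SyntheticSpec
                           ) -> tuple[list[ReferenceRecord], GroundTruthManifest]:
    """Generate records + ground-truth manifest from a synthetic spec.

    Each record gets its own background (independent child streams of the
    spec seed). For every planted variant, exactly ``round(frequency * n)``
    of the taxon's records — chosen by a seeded draw without replacement —
    carry the variant site in place of the canonical one.
    """
    root = np.random.SeedSequence(spec.seed)
    taxon_seeds = root.spawn(len(spec.taxa))
    records: list[ReferenceRecord] = []
    manifest_rows: list[dict] = []
    primers_by_name = {p.name: p for p in spec.primers}

    for taxon, tseed in zip(spec.taxa, taxon_seeds):
        n = taxon.n_records
        if n < 1:
            raise DataError(f"taxon {taxon.name!r}: n_records must be >= 1")
        rec_seeds = tseed.spawn(n + 1)
        taxon_rng = np.random.default_rng(rec_seeds[-1])
        lineage = parse_lineage(taxon.lineage)

        # one canonical site per primer, fixed for the whole taxon (binding
        # sites are conserved within a taxon, and a fixed canonical string
        # keeps planted-variant counts exact by construction); drawn jointly
        # via a prototype template so overlapping footprints stay consistent
        prototype = build_layout_template(
            spec.primers, total_length=spec.total_length,
            footprints=spec.footprints, rng=taxon_rng,
            base_freqs=spec.base_freqs,
        )
        canonical: dict[str, str] = dict(prototype.planted)

        tax_variants = [v for v in spec.variants if v.taxon == taxon.name]
        variant_sites = [v.realize(canonical[v.primer_name]) for v in tax_variants]
        # carriers drawn from a shrinking pool per primer so several variants
        # of one primer never land on the same record
        pools: dict[str, list[int]] = {}
        carriers: list[set[int]] = []
        for v in tax_variants:
            pool = pools.setdefault(v.primer_name, list(range(n)))
            k = round(v.frequency * n)
            if k > len(pool):
                raise DataError(
                    f"variant frequencies for primer {v.primer_name} in taxon "
                    f"{taxon.name} sum above 1"
                )
            chosen = taxon_rng.choice(len(pool), size=k, replace=False) if k else []
            chosen_ids = {pool[int(c)] for c in chosen}
            pools[v.primer_name] = [x for x in pool if x not in chosen_ids]
            carriers.append(chosen_ids)

        realized: dict[str, Counter] = {p.name: Counter() for p in spec.primers}
        for i in range(n):
            rng = np.random.default_rng(rec_seeds[i])
            planted = dict(canonical)
            for vi in range(len(tax_variants)):
                if i in carriers[vi]:
                    name = tax_variants[vi].primer_name
                    # re-insert last: on overlapping footprints the variant
                    # must win over the canonical site of the other primer
                    planted.pop(name, None)
                    planted[name] = variant_sites[vi]
            tpl = build_layout_template(
                spec.primers, total_length=spec.total_length,
                footprints=spec.footprints, rng=rng, base_freqs=spec.base_freqs,
                planted_override=planted,
            )
            records.append(ReferenceRecord(
                id=f"{taxon.name}_{i:04d}", sequence=tpl.sequence, lineage=lineage,
            ))
            for pname, site in tpl.planted.items():
                realized[pname][site] += 1

        # manifest: realized site strings with their true counts. A variant
        # planted at one primer can show through an overlapping primer's
        # footprint; such rows are labelled bystander.
        declared = {(v.primer_name, s) for v, s in zip(tax_variants, variant_sites)}
        for p in spec.primers:
            for site, count in sorted(realized[p.name].items(),
                                      key=lambda kv: (-kv[1], kv[0])):
                if (p.name, site) in declared:
                    kind = "variant"
                elif site == canonical[p.name]:
                    kind = "canonical"
                else:
                    kind = "bystander"
                manifest_rows.append({
                    "taxon": taxon.name, "primer": p.name,
                    "site_sequence": site, "count": count, "kind": kind,
                })

    return records, GroundTruthManifest(rows=manifest_rows)


def write_reference_set(records: Sequence[ReferenceRecord],
                        manifest: GroundTruthManifest, out_dir: str | Path,
                        prefix: str = "synthetic") -> dict[str, Path]:
    """Write FASTA + taxonomy TSV + manifest TSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / f"{prefix}_references.fasta",
        "taxonomy": out / f"{prefix}_taxonomy.tsv",
        "manifest": out / f"{prefix}_manifest.tsv",
    }
    write_fasta(records, paths["fasta"])
    write_taxonomy(records, paths["taxonomy"])
    manifest.to_tsv(paths["manifest"])
    return paths
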