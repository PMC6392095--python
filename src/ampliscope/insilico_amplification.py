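"""Binding-site discovery and in-silico PCR amplicon prediction.

A binding site is the template window a primer anneals to. Forward primers are
compared to plus-strand windows directly; for reverse primers the plus-strand
site is the reverse complement of the primer, so the scan compares
``revcomp(primer)`` against plus-strand windows (equivalently, the primer
against the reverse complement of each window). Matching is ungapped and
IUPAC-aware: a position mismatches only when the primer's and template's code
sets are disjoint, so a template ``N`` never counts against a primer.

Coordinates are 0-based half-open on the plus strand internally; text output
additionally prints 1-based inclusive columns to match the E. coli-numbering
convention implied by primer names (27F, 341F, 515F, 806R).

Amplicon prediction picks the best forward hit and the best reverse hit
downstream of it (lowest combined mismatches; ties broken by shortest product,
then leftmost) and reports the product spanning the forward footprint's 5' end
through the reverse footprint's 3' end — the "amplicon including both primer
footprints" convention used for the V1-V2 (349 bp), V3-V4 (466 bp) and V4
(292 bp) mean sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError
from .primer_core import (
    IUPAC_SETS,
    DegeneratePrimer,
    PrimerPair,
    expand,
    mismatches,
    revcomp,
    validate_iupac,
)
from .reference_io import ReferenceRecord

#: bitmask encoding: bit 0=A, 1=C, 2=G, 3=T
_CODE_MASK = {
    code: sum(1 << "ACGT".index(b) for b in bases)
    for code, bases in IUPAC_SETS.items()
}

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MIN_LEN = 50
DEFAULT_MAX_LEN = 2500


def _encode(seq: str, context: str = "") -> np.ndarray:
    up = validate_iupac(seq, context)
    return np.frombuffer(
        bytes(_CODE_MASK[c] for c in up), dtype=np.uint8
    ).copy()


def _window_mismatch_counts(template_mask: np.ndarray, query_mask: np.ndarray) -> np.ndarray:
    """Mismatch count of the query against every template window (vectorized)."""
    k = len(query_mask)
    windows = np.lib.stride_tricks.sliding_window_view(template_mask, k)
    return np.count_nonzero((windows & query_mask) == 0, axis=1)


@dataclass(frozen=True)
class BindingSiteHit:
    """A located primer footprint on a template.

    ``start``/``end`` are 0-based half-open plus-strand coordinates.
    ``site_sequence`` is re-oriented to read 5'->3' in primer orientation
    (i.e. the reverse complement of the plus-strand window for a minus-strand
    hit). ``best_expansion`` is the concrete primer formulation closest to the
    site; ``mismatch_count`` is its distance (equal to the IUPAC
    intersection-mismatch count against the degenerate primer).
    """

    record_id: str
    primer_name: str
    strand: str
    start: int
    end: int
    site_sequence: str
    mismatch_count: int
    best_expansion: str


def best_expansion_for(primer: DegeneratePrimer, site: str) -> tuple[str, int]:
    """Concrete expansion of ``primer`` with the fewest mismatches to ``site``.

    Ties broken lexicographically. The minimum equals
    ``mismatches(primer.sequence, site)`` when the site is concrete.
    """
    best = None
    best_mm = None
    for exp in primer.expansions():
        mm = mismatches(exp, site)
        if best_mm is None or mm < best_mm:
            best, best_mm = exp, mm
    return best, best_mm


def find_binding_sites(record: ReferenceRecord | str, primer: DegeneratePrimer,
                       max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                       forbid_3prime_mismatches: int | None = None
                       ) -> list[BindingSiteHit]:
    """Scan every primer-length window of the template for binding sites.

    Returns all hits with mismatch_count <= max_mismatches, sorted by
    (mismatch_count asc, start asc); empty list when none qualify. With
    ``forbid_3prime_mismatches = n``, hits carrying a mismatch within the
    primer's final n 3'-terminal bases are disqualified (off by default: plain
    mispairing counts, no 3'-end weighting).
    """
    if isinstance(record, str):
        record = ReferenceRecord(id="<anonymous>", sequence=record)
    template = record.sequence.upper()
    k = len(primer)
    if len(template) < k:
        raise DataError(
            f"template {record.id!r} ({len(template)} bp) shorter than primer "
            f"{primer.name} ({k} bp)"
        )
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")

    query = primer.plus_strand_query()
    t_mask = _encode(template, context=f"template {record.id}")
    q_mask = _encode(query)
    counts = _window_mismatch_counts(t_mask, q_mask)
    strand = "+" if primer.direction == "forward" else "-"

    hits: list[BindingSiteHit] = []
    for start in np.flatnonzero(counts <= max_mismatches):
        start = int(start)
        window = template[start:start + k]
        site = window if strand == "+" else revcomp(window)
        best_exp, mm = best_expansion_for(primer, site)
        if forbid_3prime_mismatches:
            n3 = forbid_3prime_mismatches
            tail_mm = mismatches(primer.sequence[-n3:], site[-n3:])
            if tail_mm > 0:
                continue
        hits.append(BindingSiteHit(
            record_id=record.id, primer_name=primer.name, strand=strand,
            start=start, end=start + k, site_sequence=site,
            mismatch_count=int(counts[start]), best_expansion=best_exp,
        ))
    hits.sort(key=lambda h: (h.mismatch_count, h.start))
    return hits


#: amplification failure reasons, in evaluation order
STATUS_AMPLIFIED = "amplified"
STATUS_NO_FORWARD = "no_forward_site"
STATUS_NO_REVERSE = "no_reverse_site"
STATUS_WRONG_ORIENTATION = "wrong_orientation"
STATUS_LENGTH = "length_out_of_bounds"


@dataclass(frozen=True)
class AmpliconPrediction:
    """Outcome of in-silico PCR for one template and one primer pair."""

    record_id: str
    region_name: str
    status: str
    amplicon_start: int | None = None
    amplicon_end: int | None = None
    length_with_primers: int | None = None
    forward_hit: BindingSiteHit | None = None
    reverse_hit: BindingSiteHit | None = None

    @property
    def amplified(self) -> bool:
        return self.status == STATUS_AMPLIFIED


def predict_amplicons(record: ReferenceRecord | str, pair: PrimerPair,
                      max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                      min_len: int = DEFAULT_MIN_LEN,
                      max_len: int = DEFAULT_MAX_LEN,
                      all_candidates: bool = False):
    """Predict the PCR product of ``pair`` on one template.

    The best forward hit and the best reverse hit downstream of it are chosen
    by lowest combined mismatch count; ties go to the shortest product, then
    the leftmost. Footprints may not overlap. Failures are statuses, never
    exceptions: no_forward_site, no_reverse_site, wrong_orientation (sites
    exist only in non-amplifying arrangement) or length_out_of_bounds.

    With ``all_candidates=True`` returns ``(prediction, candidates)`` where
    candidates lists every qualifying (forward, reverse) site pair.
    """
    if isinstance(record, str):
        record = ReferenceRecord(id="<anonymous>", sequence=record)
    if min_len >= max_len:
        raise ValueError(f"min_len {min_len} must be < max_len {max_len}")

    f_hits = find_binding_sites(record, pair.forward, max_mismatches)
    r_hits = find_binding_sites(record, pair.reverse, max_mismatches)

    def _fail(status):
        pred = AmpliconPrediction(record_id=record.id, region_name=pair.region_name,
                                  status=status)
        return (pred, []) if all_candidates else pred

    if not f_hits:
        return _fail(STATUS_NO_FORWARD)
    if not r_hits:
        return _fail(STATUS_NO_REVERSE)

    candidates = [
        (f, r) for f in f_hits for r in r_hits if r.start >= f.end
    ]
    if not candidates:
        return _fail(STATUS_WRONG_ORIENTATION)

    def _key(fr):
        f, r = fr
        return (f.mismatch_count + r.mismatch_count, r.end - f.start, f.start, r.start)

    candidates.sort(key=_key)
    f, r = candidates[0]
    length = r.end - f.start
    if not (min_len <= length <= max_len):
        return _fail(STATUS_LENGTH)
    pred = AmpliconPrediction(
        record_id=record.id, region_name=pair.region_name, status=STATUS_AMPLIFIED,
        amplicon_start=f.start, amplicon_end=r.end, length_with_primers=length,
        forward_hit=f, reverse_hit=r,
    )
    return (pred, candidates) if all_candidates else pred


def mean_amplicon_size(predictions: Iterable[AmpliconPrediction]
                       ) -> tuple[float, float, int, int]:
    """Mean and population SD of product length over amplified predictions.

    Returns ``(mean, sd, n_amplified, n_failed)``. SD divides by n (population
    SD). Raises when nothing amplified.
    """
    lengths = []
    n_failed = 0
    for p in predictions:
        if p.amplified:
            lengths.append(p.length_with_primers)
        else:
            n_failed += 1
    if not lengths:
        raise DataError("mean_amplicon_size: zero amplified records")
    arr = np.asarray(lengths, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0)), len(lengths), n_failed


# ---------------------------------------------------------------------------
# Text output
# ---------------------------------------------------------------------------

HIT_COLUMNS = ("record_id", "primer_name", "strand", "start", "end",
               "start_1based", "end_1based", "site_sequence", "mismatch_count",
               "best_expansion")


def hits_to_rows(hits: Iterable[BindingSiteHit]) -> list[dict]:
    """Rows with both 0-based half-open and 1-based inclusive coordinates."""
    return [
        {
            "record_id": h.record_id, "primer_name": h.primer_name,
            "strand": h.strand, "start": h.start, "end": h.end,
            "start_1based": h.start + 1, "end_1based": h.end,
            "site_sequence": h.site_sequence,
            "mismatch_count": h.mismatch_count, "best_expansion": h.best_expansion,
        }
        for h in hits
    ]


def write_hits_bed(hits: Iterable[BindingSiteHit], path: str | Path) -> None:
    """BED6 (0-based half-open, strand column); score = mismatch count."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.record_id}\t{h.start}\t{h.end}\t{h.primer_name}\t"
                     f"{h.mismatch_count}\t{h.strand}\n")


PREDICTION_COLUMNS = ("record_id", "region", "status", "amplicon_start",
                      "amplicon_end", "start_1based", "end_1based",
                      "length_with_primers", "forward_mismatches",
                      "reverse_mismatches")


def predictions_to_rows(predictions: Iterable[AmpliconPrediction]) -> list[dict]:
    rows = []
    for p in predictions:
        rows.append({
            "record_id": p.record_id, "region": p.region_name, "status": p.status,
            "amplicon_start": p.amplicon_start, "amplicon_end": p.amplicon_end,
            "start_1based": None if p.amplicon_start is None else p.amplicon_start + 1,
            "end_1based": p.amplicon_end,
            "length_with_primers": p.length_with_primers,
            "forward_mismatches": None if p.forward_hit is None else p.forward_hit.mismatch_count,
            "reverse_mismatches": None if p.reverse_hit is None else p.reverse_hit.mismatch_count,
        })
    return rows
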