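"""Per-taxon primer-pair coverage and predicted community-profile distortion.

Different hypervariable-region primer pairs fail on different lineages (the
canonical example: V1-V2 primers missing most Bifidobacteriales), so the same
community yields region-dependent profiles. The model here is deliberately
binary: a reference either amplifies under the mismatch tolerance or it does
not; a taxon's *coverage* is the amplified fraction of its references, and a
community profile is distorted by multiplying each taxon's abundance by its
coverage and renormalizing. No per-copy efficiency weighting is attempted —
the mechanism under study is presence/absence of primer compatibility.

Also provides Shannon and Simpson diversity on relative-abundance profiles and
the long-format log10-proportion table used for heat-map rendering (values
clamped at a floor, by default -4, i.e. 0.01%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError
from .insilico_amplification import predict_amplicons
from .primer_core import PrimerPair
from .reference_io import RANKS, ReferenceRecord
from .site_variation import _group_label

logger = logging.getLogger(__name__)

COVERAGE_COLUMNS = ("region_name", "taxon", "n_references", "n_amplified",
                    "coverage_fraction")


def taxon_coverage(records: Sequence[ReferenceRecord], pair: PrimerPair,
                   max_mismatches: int = 2, rank: str = "order",
                   **predict_kwargs) -> pd.DataFrame:
    """Fraction of each taxon's references predicted to amplify with ``pair``.

    Returns a DataFrame with columns region_name, taxon, n_references,
    n_amplified, coverage_fraction; records with an empty value at ``rank``
    are grouped as "unassigned". Rows sorted by taxon name.
    """
    if rank not in RANKS:
        raise DataError(f"rank {rank!r} not in lineage schema {RANKS}")
    if not records:
        raise DataError("taxon_coverage: no input records")
    tallies: dict[str, list[int]] = {}
    for rec in records:
        group = _group_label(rec.lineage, rank)
        pred = predict_amplicons(rec, pair, max_mismatches=max_mismatches,
                                 **predict_kwargs)
        n_ref, n_amp = tallies.setdefault(group, [0, 0])
        tallies[group][0] = n_ref + 1
        tallies[group][1] = n_amp + (1 if pred.amplified else 0)
    rows = [
        {"region_name": pair.region_name, "taxon": taxon,
         "n_references": n_ref, "n_amplified": n_amp,
         "coverage_fraction": n_amp / n_ref}
        for taxon, (n_ref, n_amp) in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=list(COVERAGE_COLUMNS))


@dataclass(frozen=True)
class CommunityProfile:
    """Per-taxon relative abundances summing to 1."""

    abundances: tuple[tuple[str, float], ...]
    label: str = ""

    def __post_init__(self):
        total = 0.0
        for taxon, a in self.abundances:
            if a < 0:
                raise DataError(f"negative abundance for {taxon!r}")
            total += a
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"abundances sum to {total!r}, expected 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], label: str = "",
                     normalize: bool = False) -> "CommunityProfile":
        items = sorted(mapping.items())
        if normalize:
            total = sum(v for _, v in items)
            if total <= 0:
                raise DataError("cannot normalize an all-zero profile")
            items = [(t, v / total) for t, v in items]
        return cls(abundances=tuple(items), label=label)

    def as_dict(self) -> dict[str, float]:
        return dict(self.abundances)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.abundances)


def read_profile(path, label: str = "") -> CommunityProfile:
    """Read a 2-column (taxon, fraction) TSV into a profile."""
    mapping: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, _, value = line.partition("\t")
            mapping[taxon.strip()] = float(value)
    return CommunityProfile.from_mapping(mapping, label=label or str(path),
                                         normalize=True)


def predicted_profile(profile: CommunityProfile, coverage: pd.DataFrame,
                      region: str) -> CommunityProfile:
    """Distort ``profile`` by per-taxon coverage of ``region`` and renormalize.

    abundance_i' = abundance_i * coverage_i / sum_j abundance_j * coverage_j.
    Taxa absent from the coverage table are treated as fully covered, with a
    warning. Raises when every product is zero (no taxon amplifies).
    """
    sub = coverage[coverage["region_name"] == region]
    cov = dict(zip(sub["taxon"], sub["coverage_fraction"]))
    products: dict[str, float] = {}
    for taxon, a in profile.abundances:
        c = cov.get(taxon)
        if c is None:
            logger.warning("taxon %r absent from coverage table for region %s; "
                           "assuming coverage 1", taxon, region)
            c = 1.0
        products[taxon] = a * c
    total = sum(products.values())
    if total <= 0:
        raise DataError(f"no taxon of profile {profile.label!r} amplifies in "
                        f"region {region}: all distorted abundances are zero")
    return CommunityProfile.from_mapping(
        {t: v / total for t, v in products.items()},
        label=f"{profile.label}|{region}" if profile.label else region,
    )


def shannon(profile: CommunityProfile, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i, natural log by default (0*log0 := 0)."""
    h = -sum(a * math.log(a) for _, a in profile.abundances if a > 0)
    if base is not None:
        h /= math.log(base)
    return h


def simpson(profile: CommunityProfile) -> float:
    """Simpson diversity 1 - sum p_i^2 (Gini-Simpson), in [0, 1]."""
    return 1.0 - simpson_concentration(profile)


def simpson_concentration(profile: CommunityProfile) -> float:
    """Simpson concentration sum p_i^2 (probability two draws coincide)."""
    return sum(a * a for _, a in profile.abundances)


def inverse_simpson(profile: CommunityProfile) -> float:
    """Inverse Simpson 1 / sum p_i^2 (effective number of taxa)."""
    s = simpson_concentration(profile)
    if s <= 0:
        raise DataError("inverse Simpson undefined for an empty profile")
    return 1.0 / s


def heatmap_table(profiles: Iterable[CommunityProfile],
                  floor: float = -4.0) -> pd.DataFrame:
    """Long-format log10-proportion table across samples/regions.

    The taxon universe is the union across profiles (absent taxa enter as
    zeros). Values are log10(proportion) clamped below at ``floor`` (zeros map
    to the floor); a proportion of 1.0 maps to 0. Columns: sample, taxon,
    log10_value.
    """
    profiles = list(profiles)
    universe = sorted({t for p in profiles for t in p.taxa})
    rows = []
    for p in profiles:
        d = p.as_dict()
        for taxon in universe:
            v = d.get(taxon, 0.0)
            log_v = math.log10(v) if v > 0 else floor
            rows.append({"sample": p.label, "taxon": taxon,
                         "log10_value": max(log_v, floor)})
    return pd.DataFrame(rows, columns=["sample", "taxon", "log10_value"])
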