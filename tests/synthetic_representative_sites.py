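"""SYNTHETIC stand-in primer-binding sites for lineage-specific mismatch checks.

These are not downloaded reference sequences. The Bifidobacteriales 27F-site
sequence is the well-documented real variant carried by Bifidobacterium 16S
rRNA genes (AGGGTTCGATTCTGGCTCAG: G at position 3 and C at position 7 of the
site, 1-based). The remaining groups' sites are synthetic constructions that
carry the reported number of substitutions, each placed outside the degenerate
codes' tolerance, into the canonical binding site; they reproduce the mismatch
*counts*, not the groups' actual site strings.

Each entry: (group, primer name, site sequence 5'->3' in primer orientation,
expected minimum mismatch count vs the best-matching primer expansion).
"""

from ampliscope import iupac_set, preset_primers, revcomp


def _substitute(site: str, primer_seq: str, positions: tuple[int, ...]) -> str:
    """Plant substitutions at 0-based positions, outside code tolerance."""
    out = list(site)
    for pos in positions:
        allowed = iupac_set(primer_seq[pos])
        out[pos] = sorted(set("ACGT") - allowed)[0]
    return "".join(out)


def representative_sites():
    primers = preset_primers()
    p27 = primers["27F-YM"]
    p338 = primers["338R"]
    p341 = primers["341F"]

    canon_27 = "AGAGTTTGATCCTGGCTCAG"   # an expansion of 27F-YM
    canon_338 = p338.sequence            # 338R is nondegenerate
    canon_341 = p341.expansions()[0]

    return [
        # real documented variant: 2 mismatches vs best 27f-YM expansion
        ("Bifidobacteriales", p27, "AGGGTTCGATTCTGGCTCAG", 2),
        # synthetic: 3 substitutions outside 27F-YM code tolerance
        ("Chlamydiales", p27, _substitute(canon_27, p27.sequence, (2, 6, 8)), 3),
        # synthetic: 3 substitutions in the 338R site
        ("Planctomycetales", p338, _substitute(canon_338, p338.sequence, (1, 7, 13)), 3),
        # synthetic: 2 substitutions each in the 338R and 341F sites
        ("Mollicutes RF39", p338, _substitute(canon_338, p338.sequence, (4, 10)), 2),
        ("Mollicutes RF39", p341, _substitute(canon_341, p341.sequence, (3, 9)), 2),
    ]
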