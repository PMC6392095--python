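# ampliscope

In-silico evaluation of degenerate 16S rRNA gene amplicon primers.

Amplicon surveys of bacterial communities amplify one or two hypervariable
regions of the 16S rRNA gene with "universal" degenerate primers. No primer
pair is truly universal: lineages whose binding sites carry substitutions the
degenerate codes do not absorb drop out of the survey — the classic case being
the V1-V2 forward primer 27F, which misses most *Bifidobacteriales* — and the
resulting community profile is distorted. ampliscope is a toolkit for
quantifying that risk before sequencing: it locates primer binding sites in a
reference set, profiles the site sequence variants observed per taxon,
predicts amplicons and per-taxon coverage for each region pair, predicts how a
given community profile would be distorted, and proposes primer pools that
minimize mispairing.

It is aimed at microbiome researchers choosing or troubleshooting 16S primer
pairs, and ships the five primers of the common V1-V2 / V3-V4 / V4 pairs
(27F-YM, 338R, 341F, 806RB, 515F) as presets.

## The model

A degenerate primer is a string over the 15-letter IUPAC alphabet; each letter
denotes a set of bases (Y = {C,T}, M = {A,C}, N = {A,C,G,T}, ...). Matching is
ungapped and set-based: primer position *i* mismatches template position *i*
iff their code sets are disjoint, so the mismatch count of a primer against a
concrete site equals

    d(primer, site) = min over expansions e of primer  Hamming(e, site),

the distance to the *best-matching primer formulation*. In-silico PCR scans
every template window on the appropriate strand (forward primer on the plus
strand; reverse primer as its reverse complement), keeps hits within a
mismatch tolerance, and reports the product spanning the forward footprint's
5' end through the reverse footprint's 3' end — so the predicted V1-V2, V3-V4
and V4 products on an E. coli-numbered template are 349, 466 and 292 bp
including both primer footprints.

Per-taxon coverage is the fraction of a taxon's reference sequences that
amplify; a community profile p is distorted to p'_i ∝ p_i · coverage_i.
Pool optimization is greedy weighted set cover over observed binding-site
occurrences: starting from the original primer, repeatedly add the variant (or
a conservative IUPAC merge) that exactly covers the most currently-uncovered
occurrence mass.

## Worked example

Generate a synthetic reference set of two orders (10 sequences each) in which
80% of *Bifidobacteriales* carry a two-substitution variant of the 27F-YM
binding site, then profile the site and propose a pool:

```python
import ampliscope as amp

primers = amp.preset_primers()
spec = amp.SyntheticSpec(
    taxa=(
        amp.TaxonSpec("Bifido", "k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Bifidobacteriales", 10),
        amp.TaxonSpec("Bacteroides", "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales", 10),
    ),
    primers=tuple(primers.values()),
    seed=42,
    variants=(amp.PlantedVariant(taxon="Bifido", primer_name="27F-YM",
                                 frequency=0.8, substitutions=((2, "G"), (6, "C"))),),
)
records, manifest = amp.generate_reference_set(spec)

p27 = primers["27F-YM"]
extraction = amp.extract_sites(records, p27)
lineages = {r.id: r.lineage for r in records}
table = amp.tally_variants(extraction.extractions, lineages, p27)
print(table.render())
```

```
# primer 27F-YM, grouped at rank order
occurrences  mm  site (20 nt)  dominant group(s)
         10   0  ....................  Bacteroidales
          8   2  ..G...C...C.........  Bifidobacteriales
          2   0  ..........C.........  Bifidobacteriales
```

Dots mark positions identical to the most common variant; the planted
*Bifidobacteriales* variant appears in exactly 8 of 10 sequences and sits 2
mismatches from the best-matching 27F-YM expansion. A pool of the original
primer plus that variant restores full exact-match coverage:

```python
proposal = amp.optimize_pool(table, p27, max_pool_size=3)
# proposal.pool   == ['AGAGTTTGATYMTGGCTCAG', 'AGGGTTCGATCATGGCTCAG']
# exact coverage 1.0, residual 0 mismatches
```

Coverage and profile distortion for the V1-V2 pair (1-mismatch tolerance):

```python
pairs = {p.region_name: p for p in amp.preset_pairs()}
cov = amp.taxon_coverage(records, pairs["V1-V2"], max_mismatches=1)
#  V1-V2      Bacteroidales  10  10  1.0
#  V1-V2  Bifidobacteriales  10   2  0.2

profile = amp.CommunityProfile.from_mapping(
    {"Bifidobacteriales": 0.3, "Bacteroidales": 0.7}, label="stool")
distorted = amp.predicted_profile(profile, cov, "V1-V2")
# Bifidobacteriales collapses from 30% to 7.9%; Shannon drops 0.6109 -> 0.2762
```

The same pipeline is available from the shell:

```
ampliscope simulate --seed 42 --n-records 10 --out-dir refs/
ampliscope profile-sites --fasta refs/synthetic_references.fasta \
    --taxonomy refs/synthetic_taxonomy.tsv --primer 27F-YM --out-dir out/
ampliscope pcr --pair V4 --fasta refs/synthetic_references.fasta --out-dir out/
```

Real reference sets are read the same way: FASTA plus a two-column
(ID, lineage) TSV in either the SILVA `D_0__Bacteria;D_1__...` or Greengenes
`k__Bacteria;p__...` dialect, optionally refined at 99% identity with
`ampliscope refine` before profiling.

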