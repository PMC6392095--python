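"""Binding-site scanning and in-silico PCR against exhaustive oracles."""

import numpy as np
import pytest

from ampliscope import (
    DataError,
    ReferenceRecord,
    build_layout_template,
    find_binding_sites,
    mean_amplicon_size,
    mismatches,
    predict_amplicons,
    revcomp,
)
from ampliscope.insilico_amplification import (
    STATUS_AMPLIFIED,
    STATUS_LENGTH,
    STATUS_NO_FORWARD,
    STATUS_NO_REVERSE,
    STATUS_WRONG_ORIENTATION,
)


def random_template(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_hits(template, primer, max_mm):
    """Exhaustive-window oracle using only primer_core.mismatches."""
    query = primer.sequence if primer.direction == "forward" else revcomp(primer.sequence)
    k = len(primer)
    out = []
    for start in range(len(template) - k + 1):
        window = template[start:start + k]
        mm = mismatches(query, window)
        if mm <= max_mm:
            out.append((start, mm))
    return sorted(out, key=lambda t: (t[1], t[0]))


class TestFindBindingSites:
    def test_planted_forward_site(self, primers, pairs):
        p27 = primers["27F-YM"]
        rng = np.random.default_rng(0)
        exp = p27.expansions()[1]
        template = random_template(rng, 100) + exp + random_template(rng, 200)
        hits = find_binding_sites(ReferenceRecord("t", template), p27,
                                  max_mismatches=0)
        planted = [h for h in hits if h.start == 100]
        assert len(planted) == 1
        h = planted[0]
        assert (h.strand, h.mismatch_count) == ("+", 0)
        assert h.end - h.start == len(p27)
        assert h.site_sequence == exp
        assert h.best_expansion == exp

    def test_planted_reverse_site_coordinates(self, primers):
        p338 = primers["338R"]
        rng = np.random.default_rng(1)
        template = (random_template(rng, 338) + revcomp(p338.sequence)
                    + random_template(rng, 150))
        hits = find_binding_sites(ReferenceRecord("t", template), p338,
                                  max_mismatches=0)
        planted = [h for h in hits if h.start == 338]
        assert len(planted) == 1
        h = planted[0]
        assert (h.strand, h.start, h.end, h.mismatch_count) == ("-", 338, 357, 0)
        assert h.site_sequence == p338.sequence  # re-oriented 5'->3'

    def test_no_hit_returns_empty(self, primers):
        rng = np.random.default_rng(2)
        template = random_template(rng, 400)
        p27 = primers["27F-YM"]
        oracle = brute_force_hits(template, p27, 1)
        hits = find_binding_sites(ReferenceRecord("t", template), p27,
                                  max_mismatches=1)
        assert [(h.start, h.mismatch_count) for h in hits] == oracle

    def test_template_shorter_than_primer_errors(self, primers):
        with pytest.raises(DataError):
            find_binding_sites(ReferenceRecord("t", "ACGTACGT"), primers["515F"])

    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_window_oracle_equivalence(self, seed, primers):
        """Hits equal a brute-force scan at every offset for both strands."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 2000))
        template = random_template(rng, n)
        for name in ("27F-YM", "338R", "806RB"):
            primer = primers[name]
            for max_mm in (2, 5, 8):
                hits = find_binding_sites(ReferenceRecord("t", template),
                                          primer, max_mismatches=max_mm)
                assert ([(h.start, h.mismatch_count) for h in hits]
                        == brute_force_hits(template, primer, max_mm))

    def test_coordinate_round_trip_on_revcomp(self, primers):
        """Hits on revcomp(template) map to start' = L - end."""
        rng = np.random.default_rng(9)
        p27 = primers["27F-YM"]
        template = (random_template(rng, 80) + p27.expansions()[0]
                    + random_template(rng, 120))
        L = len(template)
        fwd = find_binding_sites(ReferenceRecord("t", template), p27,
                                 max_mismatches=2)
        rc = find_binding_sites(ReferenceRecord("t", revcomp(template)), p27,
                                max_mismatches=2)
        # a forward-primer match on the plus strand has no counterpart scan on
        # the minus strand here, so compare against the reverse-direction twin
        twin = type(p27)(name="27R", sequence=p27.sequence, direction="reverse")
        rc_twin = find_binding_sites(ReferenceRecord("t", revcomp(template)),
                                     twin, max_mismatches=2)
        assert sorted(L - h.end for h in rc_twin) == sorted(h.start for h in fwd)

    def test_planted_substitutions_raise_mismatch_count(self, primers):
        p27 = primers["27F-YM"]
        exp = p27.expansions()[0]
        rng = np.random.default_rng(4)
        for k in (1, 2, 3):
            site = list(exp)
            # substitutions chosen outside degenerate-code tolerance
            positions = [0, 4, 8][:k]
            for pos in positions:
                from ampliscope import iupac_set
                forbidden = iupac_set(p27.sequence[pos])
                site[pos] = sorted(set("ACGT") - forbidden)[0]
            template = random_template(rng, 60) + "".join(site) + random_template(rng, 60)
            hits = find_binding_sites(ReferenceRecord("t", template), p27,
                                      max_mismatches=5)
            assert any(h.start == 60 and h.mismatch_count == k for h in hits)

    def test_3prime_disqualification_flag(self, primers):
        p27 = primers["27F-YM"]
        exp = p27.expansions()[0]
        site = exp[:-1] + ("A" if exp[-1] != "A" else "C")  # mismatch at 3' end
        rng = np.random.default_rng(5)
        template = random_template(rng, 50) + site + random_template(rng, 50)
        rec = ReferenceRecord("t", template)
        with_flag = find_binding_sites(rec, p27, max_mismatches=2,
                                       forbid_3prime_mismatches=2)
        without = find_binding_sites(rec, p27, max_mismatches=2)
        assert any(h.start == 50 for h in without)
        assert not any(h.start == 50 for h in with_flag)


class TestPredictAmplicons:
    def test_v4_layout_length_292(self, pairs):
        tpl = build_layout_template(pairs["V4"], total_length=1600, seed=0)
        pred = predict_amplicons(ReferenceRecord("t", tpl.sequence), pairs["V4"],
                                 max_mismatches=0)
        assert pred.status == STATUS_AMPLIFIED
        assert pred.length_with_primers == 292
        # half-open length equals 1-based inclusive accounting
        assert pred.amplicon_end - pred.amplicon_start == 292
        assert pred.amplicon_start == 514 and pred.amplicon_end == 806

    def test_only_forward_site(self, pairs, primers):
        rng = np.random.default_rng(6)
        p515 = primers["515F"]
        template = "".join(rng.choice(list("ACGT"), size=200)) \
            + p515.expansions()[0] + "".join(rng.choice(list("ACGT"), size=200))
        pred = predict_amplicons(ReferenceRecord("t", template), pairs["V4"],
                                 max_mismatches=0)
        assert pred.status == STATUS_NO_REVERSE

    def test_no_forward_site(self, pairs, primers):
        rng = np.random.default_rng(7)
        p806 = primers["806RB"]
        template = "".join(rng.choice(list("ACGT"), size=200)) \
            + revcomp(p806.expansions()[0]) + "".join(rng.choice(list("ACGT"), size=200))
        pred = predict_amplicons(ReferenceRecord("t", template), pairs["V4"],
                                 max_mismatches=0)
        assert pred.status == STATUS_NO_FORWARD

    def test_wrong_orientation(self, pairs, primers):
        rng = np.random.default_rng(8)
        p515, p806 = primers["515F"], primers["806RB"]
        template = ("".join(rng.choice(list("ACGT"), size=100))
                    + revcomp(p806.expansions()[0])
                    + "".join(rng.choice(list("ACGT"), size=100))
                    + p515.expansions()[0]
                    + "".join(rng.choice(list("ACGT"), size=100)))
        pred = predict_amplicons(ReferenceRecord("t", template), pairs["V4"],
                                 max_mismatches=0)
        assert pred.status == STATUS_WRONG_ORIENTATION

    def test_length_out_of_bounds(self, pairs):
        tpl = build_layout_template(pairs["V4"], total_length=1600, seed=0)
        pred = predict_amplicons(ReferenceRecord("t", tpl.sequence), pairs["V4"],
                                 max_mismatches=0, min_len=300, max_len=400)
        assert pred.status == STATUS_LENGTH

    def test_ties_prefer_fewest_mismatches_then_shortest(self, pairs, primers):
        p515, p806 = primers["515F"], primers["806RB"]
        rng = np.random.default_rng(10)
        fill = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        # two reverse sites downstream; nearest should win on equal mismatches
        template = (fill(50) + p515.expansions()[0] + fill(100)
                    + revcomp(p806.expansions()[0]) + fill(100)
                    + revcomp(p806.expansions()[0]) + fill(50))
        pred = predict_amplicons(ReferenceRecord("t", template), pairs["V4"],
                                 max_mismatches=0)
        assert pred.status == STATUS_AMPLIFIED
        assert pred.reverse_hit.start == 50 + 18 + 100


class TestMeanAmpliconSize:
    def test_constant_layout(self, pairs):
        preds = [
            predict_amplicons(
                ReferenceRecord(f"t{i}",
                                build_layout_template(pairs["V3-V4"],
                                                      seed=i).sequence),
                pairs["V3-V4"], max_mismatches=0)
            for i in range(4)
        ]
        mean, sd, n_amp, n_fail = mean_amplicon_size(preds)
        assert (mean, sd, n_amp, n_fail) == (466.0, 0.0, 4, 0)

    def test_population_sd(self, pairs):
        a = predict_amplicons(
            ReferenceRecord("a", build_layout_template(
                pairs["V4"], footprints={"515F": (515, 532), "806RB": (785, 804)},
                seed=1).sequence),
            pairs["V4"], max_mismatches=0)
        b = predict_amplicons(
            ReferenceRecord("b", build_layout_template(
                pairs["V4"], footprints={"515F": (515, 532), "806RB": (789, 808)},
                seed=2).sequence),
            pairs["V4"], max_mismatches=0)
        mean, sd, *_ = mean_amplicon_size([a, b])
        assert (a.length_with_primers, b.length_with_primers) == (290, 294)
        assert (mean, sd) == (292.0, 2.0)

    def test_failures_excluded_and_counted(self, pairs):
        rng = np.random.default_rng(11)
        good = predict_amplicons(
            ReferenceRecord("g", build_layout_template(pairs["V1-V2"], seed=3).sequence),
            pairs["V1-V2"], max_mismatches=0)
        bad = predict_amplicons(
            ReferenceRecord("b", "".join(rng.choice(list("ACGT"), size=800))),
            pairs["V1-V2"], max_mismatches=0)
        mean, sd, n_amp, n_fail = mean_amplicon_size([good, bad])
        assert (mean, n_amp, n_fail) == (349.0, 1, 1)

    def test_zero_amplified_errors(self, pairs):
        rng = np.random.default_rng(12)
        bad = predict_amplicons(
            ReferenceRecord("b", "".join(rng.choice(list("ACGT"), size=800))),
            pairs["V1-V2"], max_mismatches=0)
        with pytest.raises(DataError):
            mean_amplicon_size([bad])
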