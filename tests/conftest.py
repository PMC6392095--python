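"""Shared fixtures: preset primers and a small synthetic reference set."""

import pytest

import ampliscope as amp


@pytest.fixture(scope="session")
def primers():
    return amp.preset_primers()


@pytest.fixture(scope="session")
def pairs():
    return {p.region_name: p for p in amp.preset_pairs()}


@pytest.fixture(scope="session")
def small_reference_set(primers):
    """Two taxa x 10 records; a 2-substitution 27F-YM variant in 80% of one taxon."""
    spec = amp.SyntheticSpec(
        taxa=(
            amp.TaxonSpec(
                "Bifido",
                "k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Bifidobacteriales",
                10,
            ),
            amp.TaxonSpec(
                "Bacteroides",
                "D_0__Bacteria;D_1__Bacteroidetes;D_2__Bacteroidia;D_3__Bacteroidales",
                10,
            ),
        ),
        primers=tuple(primers.values()),
        seed=42,
        variants=(
            amp.PlantedVariant(
                taxon="Bifido", primer_name="27F-YM", frequency=0.8,
                substitutions=((2, "G"), (6, "C")),
            ),
        ),
    )
    records, manifest = amp.generate_reference_set(spec)
    return spec, records, manifest


@pytest.fixture()
def reference_files(tmp_path, small_reference_set):
    _, records, manifest = small_reference_set
    return amp.write_reference_set(records, manifest, tmp_path)
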