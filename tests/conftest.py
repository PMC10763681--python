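import pytest

from regscore import (
    CatalogConfig,
    FixtureParams,
    generate_fixtures,
    load_catalog,
    read_variants,
    score_variants,
)


def catalog_config_from_truth(truth, **options):
    """Catalog config pointing at every file a fixture set emitted."""
    return CatalogConfig.from_paths(
        dnase=truth.files["dnase"],
        histone=truth.files["histone"],
        tf_motif=truth.files["tf_motif"],
        abc=truth.files["abc"],
        cato=truth.files["cato"],
        eqtl=truth.files["eqtl"],
        cadd=truth.files["cadd"],
        phylop=truth.files["phylop"],
        genes=truth.files["genes"],
        **options,
    )


@pytest.fixture(scope="session")
def truth(tmp_path_factory):
    """Reference synthetic fixture set: 2,000 variants, p=0.5 per line, seed 7."""
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(FixtureParams(), out)


@pytest.fixture(scope="session")
def catalog(truth):
    return load_catalog(catalog_config_from_truth(truth))


@pytest.fixture(scope="session")
def scored(truth, catalog):
    variants = read_variants(truth.files["variants"])
    return score_variants(variants, catalog)
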