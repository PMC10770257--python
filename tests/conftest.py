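import pytest

from bomscope import lr_screen, sc_core, synthetic_data as syn


@pytest.fixture(scope="session")
def bulk_fixture():
    """Default bulk simulation (seed 42): counts, samples, truth."""
    return syn.simulate_bulk(syn.default_bulk_config(seed=42))


@pytest.fixture(scope="session")
def breast_fixture():
    """Breast-like single-cell fixture (seed 42): counts, cells, truth."""
    return syn.simulate_sc(syn.breast_like_config(seed=42))


@pytest.fixture(scope="session")
def breast_expr(breast_fixture):
    counts, _, _ = breast_fixture
    return sc_core.lognormalize(counts)


@pytest.fixture(scope="session")
def lr_fixture():
    """LR screen fixture (seed 42): counts, cells, truth, database."""
    cfg, db = syn.lr_fixture_config(seed=42)
    counts, cells, truth = syn.simulate_sc(cfg)
    return counts, cells, truth, db


@pytest.fixture(scope="session")
def lr_expr(lr_fixture):
    counts = lr_fixture[0]
    return sc_core.lognormalize(counts)


@pytest.fixture(scope="session")
def condition_fixture():
    """Single-subgroup 200v200 condition-screen fixture (seed 42)."""
    return syn.simulate_sc(syn.condition_screen_config(seed=42))


@pytest.fixture(scope="session")
def corr_fixture():
    """500-BoM-cell correlation fixture (seed 42)."""
    return syn.simulate_sc(syn.correlation_fixture_config(seed=42))


@pytest.fixture(scope="session")
def pipeline_inputs(tmp_path_factory, bulk_fixture, breast_fixture):
    """The synthetic fixtures materialized as on-disk pipeline inputs."""
    root = tmp_path_factory.mktemp("pipeline_inputs")
    bc, bs, btruth = bulk_fixture
    syn.write_bulk(bc, bs, btruth, root / "bulk")
    sc_counts, cells, struth = breast_fixture
    syn.write_sc(sc_counts, cells, struth, root / "sc")
    pairs = [(l, r) for l, r, _, _ in struth.planted_lr_pairs]
    db = syn.simulate_lr_db(pairs, 40, syn.gene_names(1500)[:300], seed=7)
    lr_screen.write_lr_db(db, root / "lr_db.csv")
    (root / "sets.gmt").write_text(
        "overlapish\tplanted overlap slice\t"
        + "\t".join(btruth.planted_overlap[:10])
        + "\nrandomset\tdecoy\tG0900\tG0901\tG0902\n"
    )
    return root, btruth, struth, pairs
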