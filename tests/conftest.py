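import pytest

from oilwatch.synthetic import GeneratorConfig, generate_corpus, generate_item_catalog


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A corpus small enough for unit tests: 3 A, 2 B, 2 C over 12 months."""
    return GeneratorConfig(
        seed=42,
        n_A=3,
        n_B=2,
        n_C=2,
        n_months=12,
        invoices_per_month=4.0,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def catalog_1000():
    """The default-sized labeled catalog (350 oil / 250 confounder / 400 unrelated)."""
    return generate_item_catalog(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def separated_features():
    """Month-level (X1, X2) features with window-level truth labels from a
    well-separated corpus (b_shift = 8, sigma_log = 0.5), computed on the
    ground-truth edible-oil partition."""
    import numpy as np

    from oilwatch.features import feature_table
    from oilwatch.synthetic import feature_truth_labels

    cfg = GeneratorConfig(seed=11, n_A=10, n_B=12, n_C=0, n_months=40,
                          p_suspicious=0.7,
                          n_oil_items=40, n_confounder_items=30, n_unrelated_items=30,
                          invoices_per_month=3.0)
    catalog, invoices, truth = generate_corpus(cfg)
    oil = {c.item_name for c in catalog if c.label == 1}
    related = [inv for inv in invoices if inv.item_name in oil]
    mids = sorted(truth.classes)
    ft = feature_table(related, mids).sort_values(["manufacturer_id", "month"]).reset_index(drop=True)
    labels = np.concatenate([
        feature_truth_labels(truth, mid, ft.loc[ft["manufacturer_id"] == mid, "month"].astype(str).tolist())
        for mid in sorted(ft["manufacturer_id"].unique())
    ])
    return ft, labels, truth
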