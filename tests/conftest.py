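import numpy as np
import pytest

from mtqscreen import boxjenkins, synthetic, workflow


@pytest.fixture(scope="session")
def synth_data():
    """Default-condition synthetic fixture: 600 compounds, 7 conditions,
    3 informative + 50 noise descriptors, effect size 2."""
    return synthetic.generate(synthetic.SynthSpec(n_compounds=600, seed=1))


@pytest.fixture(scope="session")
def trained(tmp_path_factory, synth_data):
    """One full end-to-end training run shared by pipeline-level tests."""
    dataset, block, truth = synth_data
    d = tmp_path_factory.mktemp("train")
    dataset.to_frame().drop(columns=["label", "row_index"]).to_csv(
        d / "activity.csv", index=False
    )
    boxjenkins.write_descriptor_matrix(block, d / "descriptors.csv")
    cfg = workflow.RunConfig(
        activity_table=str(d / "activity.csv"),
        descriptor_matrix=str(d / "descriptors.csv"),
        out_dir=str(d / "out"),
        selector="stepwise",
        yc_runs=5,
    )
    return workflow.run_train(cfg), truth


def two_gaussian_block(n, mu_pos, mu_neg, cov, seed, balance=0.5):
    """Two-class Gaussian sample with shared covariance; returns (block, y)."""
    rng = np.random.default_rng(seed)
    mu_pos = np.asarray(mu_pos, float)
    mu_neg = np.asarray(mu_neg, float)
    n_pos = int(round(n * balance))
    Xp = rng.multivariate_normal(mu_pos, cov, size=n_pos)
    Xn = rng.multivariate_normal(mu_neg, cov, size=n - n_pos)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(n_pos, int), -np.ones(n - n_pos, int)])
    perm = rng.permutation(n)
    names = [f"g{i}" for i in range(len(mu_pos))]
    return boxjenkins.DescriptorBlock(column_names=names, values=X[perm]), y[perm]
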