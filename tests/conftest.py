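from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cilicopd.diffexp import DatasetDEResult, DEResult
from cilicopd.expression import ExpressionDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(
    gene_ids,
    values,
    groups,
    dataset_id="D1",
    compartment="lung",
    scale="log2",
):
    """Minimal ExpressionDataset for unit tests."""
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        dataset_id=dataset_id,
        compartment=compartment,
        gene_ids=list(gene_ids),
        sample_ids=[f"S{i + 1}" for i in range(values.shape[1])],
        values=values,
        groups=list(groups),
        scale=scale,
    )


def sig_sets_with_tier_profile(n_datasets, exact_counts, seed, prefix="G"):
    """Per-dataset significant-gene sets whose exact-k gene counts are given.

    ``exact_counts[k]`` genes are made significant in exactly k randomly
    chosen datasets, so tier count (>= k) equals the suffix sum of the
    profile by construction.
    """
    rng = np.random.default_rng(seed)
    dataset_ids = [f"{prefix}DS{i + 1}" for i in range(n_datasets)]
    sig = {d: set() for d in dataset_ids}
    gi = 0
    for k in sorted(exact_counts):
        for _ in range(exact_counts[k]):
            gene = f"{prefix}{gi:04d}"
            gi += 1
            for d in rng.choice(n_datasets, size=k, replace=False):
                sig[dataset_ids[d]].add(gene)
    return sig


def de_results_from_sig_sets(sig_sets, compartment, log2fc=0.1):
    """Synthetic DatasetDEResult objects carrying only the significant genes."""
    out = []
    for ds_id, genes in sig_sets.items():
        results = {
            g: DEResult(
                gene=g,
                log2fc=log2fc,
                log10_ratio=-log2fc / 4,
                t_stat=3.0,
                df=50.0,
                p=0.01,
                q=0.04,
                significant=True,
                n_copd=30,
                n_noncopd=30,
            )
            for g in genes
        }
        out.append(
            DatasetDEResult(
                dataset_id=ds_id,
                compartment=compartment,
                results=results,
                alpha=0.05,
                sig_rule="raw_p",
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20210227)
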