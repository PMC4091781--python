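import numpy as np
import pytest

from clonarch import (
    ClonalArchitecture,
    Clone,
    WgaNoiseModel,
    build_locus_catalog,
    study_architectures,
)


def linear_architecture(subject, freqs, ntf, cluster_prefix="cluster"):
    clones = []
    for i, f in enumerate(freqs, start=1):
        clones.append(
            Clone(
                id=f"clone{i}",
                parent=None if i == 1 else f"clone{i - 1}",
                frequency=f,
                new_cluster=f"{cluster_prefix}{i}",
            )
        )
    return ClonalArchitecture(subject=subject, clones=tuple(clones), non_tumor_fraction=ntf)


@pytest.fixture(scope="session")
def archs():
    return study_architectures()


@pytest.fixture(scope="session")
def arch_a():
    """Small three-clone linear architecture for fast tests."""
    return linear_architecture("SUBA", [0.2, 0.3, 0.4], 0.1, cluster_prefix="cA")


@pytest.fixture(scope="session")
def arch_b():
    """Second subject, used as the mutual control for error estimation."""
    return linear_architecture("SUBB", [0.5, 0.3], 0.2, cluster_prefix="cB")


@pytest.fixture(scope="session")
def mini_catalog():
    """Two-subject catalog with 30-SNV clusters and small germline panels."""
    return build_locus_catalog(
        {
            "SUBA": {"cA1": 30, "cA2": 30, "cA3": 30},
            "SUBB": {"cB1": 30, "cB2": 30},
        },
        germline_het=50,
        germline_homref=20,
        germline_homvar=10,
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_noise():
    """No ADO, no sequencing error, deep uniform coverage."""
    return WgaNoiseModel(
        ado_prob=0.0,
        seq_error=0.0,
        depth_mean=200.0,
        depth_dispersion=200.0,
        locus_dropout_prob=0.0,
    )


@pytest.fixture(scope="session")
def study_noise():
    return WgaNoiseModel()
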