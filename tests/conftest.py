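import warnings

import numpy as np
import pytest

from arasig.count_model import CountMatrix, build_nona, call_ara, nb_test
from arasig.genome_intervals import closest_tss
from arasig.synthetic_data import StudyConfig, generate_study

RIP_COND = {"antiAR_1": "antiAR", "antiAR_2": "antiAR", "IgG_1": "IgG", "IgG_2": "IgG"}


def small_config(seed: int = 11, **overrides) -> StudyConfig:
    base = dict(
        seed=seed,
        n_chrom=2,
        chrom_length=8_000_000,
        n_lincrna=300,
        n_pc=300,
        n_marks=5,
        reads_per_track=80_000,
        n_tads=60,
        mark_enrichment_fold=10.0,
        min_tad_length=100_000,
    )
    base.update(overrides)
    return StudyConfig(**base)


@pytest.fixture(scope="session")
def study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def analysis(study):
    """ARA/NonA calls, neighbor pairs and track lookup for the shared study."""
    rip = nb_test(study.rip_counts, "antiAR")
    ara = call_ara(rip, fdr=0.10)
    nona = build_nona(rip, study.rip_counts, n=len(ara), exclude=ara)
    pairs = closest_tss(study.lincs, study.pcs)
    return {
        "rip": rip,
        "ara": ara,
        "nona": nona,
        "pairs": pairs,
        "tracks": {t.mark: t for t in study.tracks},
        "by_gene": {t.gene_id: t for t in study.annotation},
        "truth_ara": set(study.truth.index[study.truth["is_ara"]]),
    }


def nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mean, dtype=float)), size=size)


def null_rip_matrix(seed: int, n: int = 2000, mu: float = 100.0, disp: float = 0.1) -> CountMatrix:
    rng = np.random.default_rng(seed)
    counts = nb_counts(rng, np.full((n, 4), mu), disp)
    return CountMatrix(
        [f"g{i}" for i in range(n)], list(RIP_COND), counts, dict(RIP_COND)
    )


@pytest.fixture(autouse=True)
def _quiet_small_shuffle_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fewer than 100 shuffles")
        warnings.filterwarnings("ignore", message=".*had no neighbor pair.*")
        yield
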