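"""Shared fixtures: synthetic fibrils, shift lists and simulated spectra.

Heavy end-to-end objects (fold-pair spectra, full restraint pipelines) are
session-scoped so the classification and soundness tests share one
computation.
"""

from dataclasses import replace

import pytest

from fibrilscope.restraint_gen import check_violations, generate_restraints
from fibrilscope.spectrum_sim import ExperimentSpec, enumerate_cross_peaks
from fibrilscope.synthetic import (
    FoldTemplate,
    default_template,
    make_fibril,
    make_fold_pair,
    make_noisy_spectrum,
    make_resonances,
    perturb_peaks,
)


@pytest.fixture(scope="session")
def template() -> FoldTemplate:
    return default_template()


@pytest.fixture(scope="session")
def fibril(template):
    return make_fibril(template)


@pytest.fixture(scope="session")
def resonances(template):
    return make_resonances(template)


@pytest.fixture(scope="session")
def small_template() -> FoldTemplate:
    """A short two-strand hairpin: fast enough for per-test pipelines."""
    return FoldTemplate(
        sequence="GAVKTVEGAGSIAAATGFVK",
        first_residue=75,
        strand_segments=((76, 82), (86, 93)),
        n_protomers=3,
    )


@pytest.fixture(scope="session")
def small_fibril(small_template):
    return make_fibril(small_template)


@pytest.fixture(scope="session")
def small_resonances(small_template):
    return make_resonances(small_template)


@pytest.fixture(scope="session")
def cc50() -> ExperimentSpec:
    return ExperimentSpec(kind="CC_DARR", mixing_ms=50)


@pytest.fixture(scope="session")
def fold_pair_spectra():
    """CC 50 ms spectra for 2 folds x 3 jitter seeds, labelled A*/B*."""
    a, b = make_fold_pair()
    exp = ExperimentSpec(kind="CC_DARR", mixing_ms=50)
    specs = []
    for name, t in (("A", a), ("B", b)):
        res = make_resonances(t)
        for seed in (1, 2, 3):
            tt = replace(t, seed=seed, jitter_sigma=0.3)
            specs.append(
                make_noisy_spectrum(make_fibril(tt), res, exp, snr=20,
                                    seed=seed * 10 + (name == "B"), id=f"{name}{seed}")
            )
    return specs


@pytest.fixture(scope="session")
def fold_pair_protomers():
    """One protomer chain per fold-pair structure, labelled A*/B*."""
    a, b = make_fold_pair()
    chains = []
    for name, t in (("A", a), ("B", b)):
        for seed in (1, 2, 3):
            tt = replace(t, seed=seed, jitter_sigma=0.3)
            model = make_fibril(tt).models[0]
            chains.append((f"{name}{seed}", list(model.chains.values())[0]))
    return chains


@pytest.fixture(scope="session")
def restraint_pipeline(template, fibril, resonances):
    """Noiseless and noisy end-to-end restraint runs on the default fibril."""
    lists = {
        m: enumerate_cross_peaks(fibril, resonances,
                                 ExperimentSpec(kind="CC_DARR", mixing_ms=m))
        for m in (50, 500)
    }
    clean_rest, clean_summary = generate_restraints(lists, resonances)
    clean_report = check_violations(clean_rest, fibril)
    noisy_lists = {m: perturb_peaks(pl, pos_sigma=0.05, snr=10, seed=7 + m)
                   for m, pl in lists.items()}
    noisy_rest, _ = generate_restraints(noisy_lists, resonances)
    noisy_report = check_violations(noisy_rest, fibril)
    return {
        "peak_lists": lists,
        "clean": (clean_rest, clean_summary, clean_report),
        "noisy": (noisy_rest, noisy_report),
    }
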