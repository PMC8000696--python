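import numpy as np
import pytest

from quenchfit import (EquilibriumModel, SolutionComposition, Species,
                       TitrationProtocol, drug_presets, preset_protocol,
                       simulate_titration)


@pytest.fixture(scope="session")
def one_to_one_model():
    return EquilibriumModel(species=(Species(1, 1, log_kb=6.0),))


@pytest.fixture(scope="session")
def two_site_model():
    # stepwise 5.74 / 4.57 -> cumulative beta2 = 10.31
    return EquilibriumModel(species=(Species(1, 1, log_kb=5.74),
                                     Species(1, 2, log_kb=10.31)))


@pytest.fixture(scope="session")
def naproxen_clean_dataset():
    truth = drug_presets(20.0, noise_sd_fraction=0.0)["naproxen"]
    protocol = preset_protocol("naproxen", seed=7, temperature_C=20.0)
    return truth, simulate_titration(protocol, truth)


@pytest.fixture(scope="session")
def diflunisal_clean_dataset():
    truth = drug_presets(20.0, noise_sd_fraction=0.0)["diflunisal"]
    protocol = preset_protocol("diflunisal", seed=7, temperature_C=20.0)
    return truth, simulate_titration(protocol, truth)


@pytest.fixture(scope="session")
def diflunisal_noisy_dataset():
    truth = drug_presets(20.0)["diflunisal"]
    protocol = preset_protocol("diflunisal", seed=3, temperature_C=20.0)
    return truth, simulate_titration(protocol, truth)


def nested_bisection_oracle(model, total_s, total_q, tol=1e-14):
    """Independent speciation oracle: bisection on free S, with free Q
    solved by an inner bisection at each trial free S."""
    betas = [(sp.s, sp.q, 10.0 ** sp.log_kb) for sp in model.complexes]

    def q_balance(fs, fq):
        return fq + sum(q * b * fs ** s * fq ** q for s, q, b in betas) - total_q

    def solve_fq(fs):
        lo, hi = 0.0, total_q
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if q_balance(fs, mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def s_balance(fs):
        fq = solve_fq(fs)
        return fs + sum(s * b * fs ** s * fq ** q for s, q, b in betas) - total_s

    lo, hi = 0.0, total_s
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if s_balance(mid) > 0:
            hi = mid
        else:
            lo = mid
    fs = 0.5 * (lo + hi)
    fq = solve_fq(fs)
    complexes = {(s, q): b * fs ** s * fq ** q for s, q, b in betas}
    return fs, fq, complexes
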