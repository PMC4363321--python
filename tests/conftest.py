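import numpy as np
import pytest

from relca import (
    CaseConfig,
    ComparisonDesign,
    Exchange,
    Flow,
    UnitProcess,
    build_system,
    generate_case,
    run_comparison,
)

KWH = Flow("electricity", "electricity", "product", "kWh")
FISH = Flow("fish", "fish", "product", "tonne")
CO2 = Flow("co2", "carbon dioxide", "elementary", "kg", "air")
CH4 = Flow("ch4", "methane", "elementary", "kg", "air")


def two_process_processes():
    """Electricity (1 kWh, 0.5 kg CO2/kWh) feeding a farm (1 t fish,
    500 kWh, 10 kg CH4)."""
    electricity = UnitProcess(
        "electricity", "electricity",
        Exchange(KWH, 1.0, "prod.electricity"),
        (Exchange(CO2, 0.5, "elec.co2"),),
    )
    farming = UnitProcess(
        "farming", "farming",
        Exchange(FISH, 1.0, "prod.farming"),
        (Exchange(KWH, -500.0, "farm.elec"), Exchange(CH4, 10.0, "farm.ch4")),
    )
    return [electricity, farming]


@pytest.fixture
def two_process_system():
    return build_system("demo", two_process_processes(), ("fish", 1.0))


@pytest.fixture(scope="session")
def default_case():
    return generate_case()


@pytest.fixture(scope="session")
def null_case():
    return generate_case(CaseConfig(true_effect=0.0))


@pytest.fixture(scope="session")
def mc_results(default_case):
    """Dependent and independent result sets on the default case, shared
    across tests to keep the suite fast."""
    out = {}
    for mode in ("dependent", "independent"):
        design = ComparisonDesign(
            alternatives=default_case.systems,
            characterization=default_case.characterization,
            n_runs=400,
            mode=mode,
            master_seed=11,
        )
        out[mode] = run_comparison(design)
    return out


def identical_alternatives():
    """Two copies of the same fully-shared stochastic system."""
    from relca import lognormal_from_mean

    spec = lognormal_from_mean(0.5, 1.4)
    systems = []
    for aid in ("a", "b"):
        electricity = UnitProcess(
            "electricity", "electricity",
            Exchange(KWH, 1.0, "prod.electricity"),
            (Exchange(CO2, spec.mean, "shared.elec.co2", spec),),
        )
        farming = UnitProcess(
            "farming", "farming",
            Exchange(FISH, 1.0, "prod.farming"),
            (Exchange(KWH, -500.0, "farm.elec"), Exchange(CH4, 10.0, "farm.ch4")),
        )
        systems.append(build_system(aid, [electricity, farming], ("fish", 1.0)))
    return systems


@pytest.fixture
def identical_pair():
    return identical_alternatives()


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
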