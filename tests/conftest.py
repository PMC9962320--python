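import numpy as np
import pytest

from mtxpk import (
    CovariateRecord,
    build_model_catalog,
    get_model,
    regimen_from_dose,
)


@pytest.fixture(scope="session")
def catalog():
    return build_model_catalog()


@pytest.fixture(scope="session")
def reference_child():
    """A typical validation-cohort child (median covariates)."""
    return CovariateRecord(
        patient_id="REF",
        sex="M",
        age=5.5,
        weight=19.0,
        height=113.0,
        scr_mgdl=0.31,
        oh=200.0,
        risk_group="LR",
    )


@pytest.fixture(scope="session")
def medellin(catalog):
    return get_model("medellin", catalog)


@pytest.fixture(scope="session")
def jonsson(catalog):
    return get_model("jonsson", catalog)


@pytest.fixture
def single_course():
    """One 3 g/m^2 HD-MTX course at BSA 0.77 m^2."""
    return regimen_from_dose(3.0, 0.77)


def random_structural_params(rng: np.random.Generator, n_compartments: int):
    """Randomized positive parameter sets for solver cross-checks."""
    from mtxpk import StructuralParams

    if n_compartments == 2:
        values = {
            "CL": rng.uniform(1.0, 10.0),
            "V1": rng.uniform(5.0, 30.0),
            "Q": rng.uniform(0.05, 5.0),
            "V2": rng.uniform(1.0, 50.0),
        }
    else:
        values = {
            "CL": rng.uniform(1.0, 10.0),
            "V1": rng.uniform(5.0, 30.0),
            "Q1": rng.uniform(0.05, 5.0),
            "V2": rng.uniform(1.0, 50.0),
            "Q2": rng.uniform(0.05, 5.0),
            "V3": rng.uniform(1.0, 50.0),
        }
    return StructuralParams(
        model_name="random",
        values=values,
        etas=np.zeros(0),
        n_compartments=n_compartments,
        parameterization="clearance-volume",
    )
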