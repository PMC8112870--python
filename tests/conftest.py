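import pytest

from multidec.combine import NonDecisionSpec
from multidec.ddm_core import BoundSpec, DDMParams, SolverConfig, first_passage_solve
from multidec.synthetic_data import DesignGrid


@pytest.fixture(scope="session")
def coarse_cfg() -> SolverConfig:
    """Solver config for quick checks: coarse but conservation-clean."""
    return SolverConfig(dt=2e-3, t_max=4.0, n_grid=128)


@pytest.fixture(scope="session")
def flat_params() -> DDMParams:
    return DDMParams(kappa=10.0, s0=0.0, bound=BoundSpec.flat(0.6), dimension_label="motion")


@pytest.fixture(scope="session")
def collapsing_params() -> DDMParams:
    return DDMParams(
        kappa=10.0, s0=0.0,
        bound=BoundSpec(form="logistic", u=0.9, a=1.5, d=1.2),
        dimension_label="motion",
    )


@pytest.fixture(scope="session")
def serial_gen_params() -> dict:
    """Representative generating parameters for serial/parallel tasks."""
    return {
        "motion": DDMParams(
            11.0, 0.0, BoundSpec(form="logistic", u=0.9, a=1.2, d=1.5), "motion"
        ),
        "color": DDMParams(
            9.0, 0.0, BoundSpec(form="logistic", u=0.8, a=1.0, d=1.4), "color"
        ),
        "nd": NonDecisionSpec(0.32, 0.06),
    }


@pytest.fixture(scope="session")
def small_design() -> DesignGrid:
    return DesignGrid(motion_levels=(0.064, 0.512), color_levels=(0.064, 0.472))


@pytest.fixture(scope="session")
def fp_pair(serial_gen_params, coarse_cfg):
    """A matched pair of motion/color first-passage solutions."""
    fp_m = first_passage_solve(serial_gen_params["motion"], 0.128, coarse_cfg)
    fp_c = first_passage_solve(serial_gen_params["color"], 0.25, coarse_cfg)
    return fp_m, fp_c
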