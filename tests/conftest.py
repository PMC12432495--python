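import numpy as np
import pytest

from fumebox.models import ModelConfig, ModelKind, SourceSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_config(rng, kind: ModelKind) -> ModelConfig:
    """A random physically valid model configuration."""
    V_room = rng.uniform(30.0, 300.0)
    ach = rng.uniform(1.0, 60.0)
    if kind is ModelKind.ONE_BOX:
        return ModelConfig(kind, V_room=V_room, ach=ach)
    V_NF = rng.uniform(0.5, 0.3 * V_room)
    beta = rng.uniform(2.0, 40.0)
    if kind is ModelKind.TWO_BOX:
        return ModelConfig(kind, V_room=V_room, ach=ach, V_NF=V_NF, beta=beta)
    return ModelConfig(kind, V_room=V_room, ach=ach, V_NF=V_NF, beta=beta,
                       Q_lev=rng.uniform(0.5, 20.0), epsilon=rng.uniform(0.0, 0.99))


def random_schedule(rng, T_shift: float = 480.0) -> SourceSchedule:
    t_g = rng.uniform(10.0, 0.8 * T_shift)
    t_start = rng.uniform(0.0, T_shift - t_g)
    return SourceSchedule(S_m=rng.uniform(10.0, 2000.0), t_g=t_g,
                          t_start=t_start, T_shift=T_shift)
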