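import numpy as np
import pytest

import sensgame as sg

DAWKINS_RULES = (50.0, 0.0, -100.0, -10.0)


@pytest.fixture(scope="session")
def hawk_dove() -> sg.StaticGame:
    """Hawk-Dove game from the classic +50/0/-100/-10 scoring."""
    return sg.hawk_dove_game(sg.ContestRules(*DAWKINS_RULES))


@pytest.fixture(scope="session")
def printed_params() -> sg.MigraineGameParams:
    return sg.MigraineGameParams(c_m=0.3, c_n=0.2, d_m_prime=0.5)


@pytest.fixture(scope="session")
def gen_game() -> sg.GeneralizedMigraineGame:
    return sg.GeneralizedMigraineGame(f_n=1.2, f_m=1.1, d_m=1.0, d_n=0.9, d_m_prime=0.5)


def random_general_games(n: int, entropy: int = 2024):
    """Deterministic stream of valid constant-fitness migraineur games."""
    return [
        sg.generate_random_scenario(
            np.random.SeedSequence(entropy=(entropy, k)), "migraine_general"
        )
        for k in range(n)
    ]
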