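import random

import pytest

from vennkit import LABELS, SetFamily, build_family


def random_family(rng: random.Random, n: int | None = None, max_elements: int = 200) -> SetFamily:
    """A seeded random family: n sets drawing from a shared element pool.

    The pool is small relative to the draw counts so that overlaps of
    every order actually occur.
    """
    n = n if n is not None else rng.randint(1, 6)
    pool = [f"el{i}" for i in range(rng.randint(1, max_elements))]
    entries = []
    for i in range(n):
        k = rng.randint(0, len(pool))
        entries.append((f"set{i}", "\n".join(rng.sample(pool, k))))
    return build_family(entries)


@pytest.fixture
def two_set_family() -> SetFamily:
    return build_family([("left", "x\ny"), ("right", "y\nz")])


@pytest.fixture
def empty_family_4() -> SetFamily:
    return build_family([(name, "") for name in ("w", "x", "y", "z")])
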