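import numpy as np
import pytest

from flavoscan import build_profile, training_alignment


@pytest.fixture(scope="session")
def profile():
    """A seeded riboswitch-like profile shared across scanning tests."""
    return build_profile(training_alignment(12345), pseudocount=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def plant_local_identity(prototype, identity, coverage, rng, tol=0.005):
    """A candidate whose *local-alignment* identity/coverage to ``prototype``
    sit at the requested levels (local identity runs a little above the
    substitution rate because optimal alignments trim mismatching ends, so
    the mutation target is adjusted until the measured value lands)."""
    from flavoscan.align import align_local
    from flavoscan.synthetic import mutate_to_identity

    kept = prototype[: int(round(coverage * len(prototype)))]
    target = identity
    for _ in range(40):
        cand = mutate_to_identity(kept, target, rng)
        r = align_local(cand, prototype)
        if r.identity > identity + tol:
            target -= 0.005
        elif r.identity < identity - tol:
            target += 0.005
        else:
            # end-trimming shaves a little coverage at low identity
            assert coverage - 0.08 <= r.coverage <= coverage + 0.05
            return cand, r
    raise AssertionError(f"could not realize local identity {identity}")
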