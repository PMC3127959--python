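import pytest

from chunkalign.io_formats import ReferenceSeq
from chunkalign.seeding import IndexCache
from chunkalign.simulate import gen_reference


@pytest.fixture(scope="session")
def small_ref() -> ReferenceSeq:
    """A 2 kb random reference shared by fast unit tests."""
    return gen_reference(2000, gc=0.5, rng_seed=42)


@pytest.fixture(scope="session")
def small_cache(small_ref) -> IndexCache:
    return IndexCache([small_ref])
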