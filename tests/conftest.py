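import pytest

from pollentyping import Marker, MarkerMap


@pytest.fixture
def small_map() -> MarkerMap:
    """Six SNPs at round positions for hand-checkable classification."""
    markers = [
        Marker("m1", 100, "A", "G"),
        Marker("m2", 500, "C", "T"),
        Marker("m3", 1000, "A", "T"),
        Marker("m4", 1500, "G", "C"),
        Marker("m5", 2000, "T", "A"),
        Marker("m6", 2600, "G", "A"),
    ]
    return MarkerMap("toy", markers)


@pytest.fixture
def dense_map() -> MarkerMap:
    """40 evenly spaced SNPs spanning ~4.7 kb, a realistic hotspot map."""
    markers = [Marker(f"m{i}", 1000 + 120 * i, "A", "G") for i in range(40)]
    return MarkerMap("dense", markers)
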