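import pandas as pd
import pytest
from hypothesis import settings

from tugtrap.pipeline import analyze_trace
from tugtrap.synth import TraceGenConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """Six default-condition traces with detection results, shared read-only."""
    data = generate_dataset(6, TraceGenConfig(n_events=30), seed=42)
    stalls, pairs = [], []
    for trace in data["traces"]:
        result = analyze_trace(trace)
        stalls.extend(result["stalls"])
        pairs.extend(result["pairs"])
    return {
        "traces": data["traces"],
        "truth": data["truth"],
        "stalls": stalls,
        "pairs": pairs,
    }
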