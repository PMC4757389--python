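import hypothesis
import pytest

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")

from pherotome import synthetic  # noqa: E402


@pytest.fixture(scope="session")
def canonical_proteins() -> dict[str, str]:
    return {label: synthetic.canonical_protein(label) for label in synthetic.CLASS_LABELS}


@pytest.fixture(scope="session")
def reference_panel() -> list[tuple[str, str]]:
    return synthetic.build_reference_panel()
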