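import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from shieldseq.editor_model import EditorSpec
from shieldseq.geometry import WindowSpec, resolve_window
from shieldseq.simulate import demo_geometry


@pytest.fixture(scope="session")
def k352_site():
    """Demo amplicon/protospacer/codon map around the K352 codon."""
    return demo_geometry("K352")


@pytest.fixture(scope="session")
def n286_site():
    """Demo geometry around the I283/H285/N286 codons (bystander triple)."""
    return demo_geometry("N286")


@pytest.fixture(scope="session")
def k352_window(k352_site):
    """Resolved quantification window (centre -10, size 15) at the K352 site."""
    amplicon, proto, _ = k352_site
    return resolve_window(WindowSpec(center_offset=-10, size=15), proto, amplicon)


@pytest.fixture(scope="session")
def abe():
    return EditorSpec(chemistry="ABE")
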