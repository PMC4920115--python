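import pytest

from tandemhor._align import warmup
from tandemhor.detect import MonomerModel
from tandemhor.pipeline import PipelineConfig, process_read
from tandemhor.simulate import SyntheticReadSpec, make_monomer_family, synthesize_read


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Pay the JIT compilation cost once, before any timed test."""
    warmup()


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(min_read_length=0)


def run_spec(spec: SyntheticReadSpec, config: PipelineConfig | None = None):
    """Synthesize one read and push it through the full per-read pipeline."""
    read, truth = synthesize_read(spec)
    models = [
        MonomerModel(f"m{i}", s) for i, s in enumerate(make_monomer_family(spec))
    ]
    result = process_read(
        read, models=models, config=config or PipelineConfig(min_read_length=0)
    )
    return read, truth, result
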