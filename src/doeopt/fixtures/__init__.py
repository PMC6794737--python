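"""Bundled benchmark fixture configurations.

The five pipeline configs replicate the factor spaces and response
declarations of the published benchmark cases (bounds and types only; the
real response surfaces are not claimed).  ``reported_results.yaml`` carries
the published default/optimized response values used by the
percent-improvement helpers.
"""

from importlib import resources

import yaml

CASES = (
    "case1_assembly",
    "case2_scaffolding",
    "case3_classification",
    "case4_calling",
    "case4_filtering",
)


def fixture_text(name: str) -> str:
    """Raw YAML text of a bundled fixture (e.g. ``case1_assembly``)."""
    return (
        resources.files(__package__).joinpath(f"{name}.yaml").read_text()
    )


def load_fixture_config(name: str):
    """Parsed :class:`~doeopt.pipeline.PipelineConfig` for a bundled case."""
    from ..pipeline import load_config

    return load_config(fixture_text(name))


def reported_results() -> dict:
    """Published default/optimized response values per case."""
    return yaml.safe_load(fixture_text("reported_results"))
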