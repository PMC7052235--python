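"""Shared fixtures: simulated families at the default study conditions.

The expensive artifacts (full default family, its emitted files and the
pipeline run over them) are session-scoped so the whole suite pays for
them once.
"""

from __future__ import annotations

import pytest

from embryoscreen.simulate import SimParams, emit, simulate_family


@pytest.fixture(scope="session")
def default_family(tmp_path_factory):
    """Default three-embryo family, emitted to disk, with its path map."""
    params = SimParams(seed=1)
    fam = simulate_family(params)
    outdir = tmp_path_factory.mktemp("default_family")
    paths = emit(fam, str(outdir))
    return fam, paths


@pytest.fixture(scope="session")
def default_report(default_family):
    """Pipeline output over the default family."""
    import yaml

    from embryoscreen.report import run_pipeline

    _, paths = default_family
    with open(paths["config"]) as fh:
        config = yaml.safe_load(fh)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def clean_family(tmp_path_factory):
    """Artifact-free single-embryo family: no dropout, no false hets.

    Mendelian-clean apart from planted de novos, so pipeline candidate
    sets can be compared against truth exactly.
    """
    from embryoscreen.simulate import default_planted_variants

    planted = [s for s in default_planted_variants() if not s.in_dropout]
    params = SimParams(
        seed=7,
        embryo_sexes=("male",),
        artifact_het_rate=0.0,
        dropout_regions=0,
        planted_variants=planted,
    )
    fam = simulate_family(params)
    outdir = tmp_path_factory.mktemp("clean_family")
    paths = emit(fam, str(outdir))
    return fam, paths


@pytest.fixture(scope="session")
def loaded_records(default_family):
    """Records + annotations + pedigree parsed back from the emitted files."""
    from embryoscreen.trio_io import read_annotations, read_pedigree, read_trio_vcf

    _, paths = default_family
    pedigree = read_pedigree(paths["pedigree"])
    records = list(read_trio_vcf(paths["vcf"], pedigree))
    annotations = read_annotations(paths["annotations"])
    return pedigree, records, annotations
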