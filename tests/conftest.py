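import numpy as np
import pandas as pd
import pytest

from orchardkin.relatedness import AlleleFrequencyReference
from orchardkin.synthetic_data import SimulationConfig, make_fixture


def make_ref(p):
    p = np.asarray(p, dtype=float)
    return AlleleFrequencyReference(
        [f"chr1:{1000+10*j}:A:G" for j in range(p.size)], p, ["ref1", "ref2"]
    )


@pytest.fixture(scope="session")
def orchard(tmp_path_factory):
    """A seeded synthetic orchard at reduced problem size, plus its pipeline run.

    Study-condition parameters (28 parents with the census ramet counts,
    33.6% external pollen, natural same-genotype mating, 5% allele error,
    depth floor 8) at 5000 loci and 60 sampled seedlings so the full
    pipeline fits in the test budget.
    """
    from orchardkin.pipeline import PipelineConfig, run_pipeline

    root = tmp_path_factory.mktemp("orchard")
    config = SimulationConfig(n_loci=5000, n_offspring=60, n_reference=80, seed=11)
    paths = make_fixture(config, root / "sim")
    out = run_pipeline(
        PipelineConfig(
            vcf=paths["vcf"], metadata=paths["meta"], outdir=str(root / "out"), seed=5
        )
    )
    truth = pd.read_csv(paths["pedigree"], sep="\t")
    return {
        "config": config,
        "paths": paths,
        "outdir": out,
        "pedigree": pd.read_csv(out / "pedigree.tsv", sep="\t"),
        "truth": truth,
    }
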