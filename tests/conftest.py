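import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gridrun as g

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


WORKED_EXAMPLE_XML = """\
<experiments>
  <dataset path="{dataset}"/>
  <evaluation strategy="loocv"/>
  <algorithm key="knn">
    <param name="k" start="1" step="1" end="10"/>
  </algorithm>
  <algorithm key="stump">
    <param name="min_leaf" start="1" step="1" end="10"/>
  </algorithm>
  <output dir="{output}"/>
</experiments>
"""


@pytest.fixture
def worked_example_xml():
    """Two algorithms, one 10-value interval range each, LOOCV: a 20-experiment grid."""
    return WORKED_EXAMPLE_XML.format(dataset="demo.arff", output="results")


@pytest.fixture
def worked_example_spec(worked_example_xml):
    return g.parse_spec(worked_example_xml)


@pytest.fixture
def small_dataset():
    """Well-separated 3-class dataset, 40 rows, mixed attribute kinds."""
    return g.make_synthetic(
        n_samples=40, n_numeric=4, n_nominal=2, n_classes=3,
        class_sep=3.0, missing_rate=0.05, seed=7,
    )


@pytest.fixture
def runnable_spec(tmp_path, small_dataset):
    """Worked-example grid wired to a real dataset under tmp_path."""
    arff = tmp_path / "demo.arff"
    arff.write_text(g.write_arff(small_dataset), encoding="utf-8")
    xml = WORKED_EXAMPLE_XML.format(dataset=arff, output=tmp_path / "out")
    return g.parse_spec(xml)


def random_dataset(rng, n_rows=None, n_classes=None):
    """Small random dataset for property tests (shared helper)."""
    n_rows = n_rows or int(rng.integers(6, 20))
    n_classes = n_classes or int(rng.integers(2, 4))
    return g.make_synthetic(
        n_samples=n_rows,
        n_numeric=int(rng.integers(1, 4)),
        n_nominal=int(rng.integers(0, 3)),
        n_classes=n_classes,
        class_sep=float(rng.uniform(0, 4)),
        missing_rate=float(rng.uniform(0, 0.2)),
        seed=int(rng.integers(0, 2**31)),
    )
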