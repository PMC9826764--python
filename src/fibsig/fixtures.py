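"""Packaged published reference lists for the paired-biopsy fibrosis cohort.

Available fixtures:

``table1_samples``
    Sample annotation of the 44 paired intestinal biopsies (22 patients,
    one terminal-ileum and one sigmoid sample each; 7 CD, 6 UC, 9 controls).
``table2_fibsig``
    The 241-gene cross-disease fibrotic signature (FIBSig).
``table3_m1``
    The 112-gene M1 co-expression module (a subset of FIBSig).
``hub21``
    The 21 hub genes of the M1 interaction subnetwork.
``shared20``
    The 20 FIBSig genes co-expressed in both ileum and sigmoid.
``cd7``
    The 7 genes significant in all nine Crohn's-disease cohorts.
"""

from __future__ import annotations

from importlib import resources

from .types import GeneSet, SampleAnnotation

_GENE_LIST_FIXTURES = {
    "table2_fibsig": "table2_fibsig.txt",
    "table3_m1": "table3_m1.txt",
    "hub21": "hub21.txt",
    "shared20": "shared20.txt",
    "cd7": "cd7.txt",
}

FIXTURE_NAMES = ("table1_samples",) + tuple(_GENE_LIST_FIXTURES)


def load_fixture(name: str) -> GeneSet | SampleAnnotation:
    """Load a packaged fixture by name (see module docstring)."""
    from . import io  # local import avoids a cycle at package import time

    if name == "table1_samples":
        ref = resources.files("fibsig.data") / "table1_samples.tsv"
        with resources.as_file(ref) as path:
            return io.read_sample_annotation(path)
    if name in _GENE_LIST_FIXTURES:
        ref = resources.files("fibsig.data") / _GENE_LIST_FIXTURES[name]
        with resources.as_file(ref) as path:
            return io.read_gene_list(path, name=name)
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
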