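import numpy as np
import pytest

import gxratio as gx


@pytest.fixture(scope="session")
def tiny_table() -> gx.CTTable:
    return gx.make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_expr(tiny_table) -> gx.ExpressionMatrix:
    return gx.ct_to_relative(tiny_table)


@pytest.fixture(scope="session")
def paperlike_table() -> gx.CTTable:
    return gx.make_fixture("paperlike", seed=7)


@pytest.fixture(scope="session")
def paperlike_expr(paperlike_table) -> gx.ExpressionMatrix:
    return gx.ct_to_relative(paperlike_table)


@pytest.fixture(scope="session")
def ibd_expr(paperlike_expr) -> gx.ExpressionMatrix:
    """CD+UC pooled as IBD, against CTRL and IBS."""
    return gx.merge_labels(paperlike_expr, {"CD": "CD", "UC": "CD"})


@pytest.fixture(scope="session")
def cd_ctrl_panelled(paperlike_expr):
    """A trained CD-vs-CTRL panel plus the expression subset it was fit on."""
    keep = [s for s in paperlike_expr.subject_ids
            if paperlike_expr.groups[s] in ("CD", "CTRL")]
    sub = paperlike_expr.subset(keep)
    candidates = gx.search_candidates(sub, "CD", "CTRL", reps=30, top_k=100,
                                      seed=11)[:100]
    panel = gx.select_panel(candidates, sub, "CD", "CTRL")
    return panel, sub


def small_grid():
    return tuple((w, c)
                 for w in (0.0625, 0.25, 1.0, 4.0)
                 for c in (0.25, 1.0, 4.0, 16.0))


@pytest.fixture(scope="session")
def reduced_grid():
    return small_grid()


def random_expression(rng: np.random.Generator, n_subjects: int, probes,
                      groups=None) -> gx.ExpressionMatrix:
    """Random positive expression matrix for property tests."""
    subjects = [f"S{i}" for i in range(n_subjects)]
    levels = 2.0 ** rng.normal(0.0, 1.0, size=(n_subjects, len(probes)))
    groups = groups or {s: "CTRL" for s in subjects}
    return gx.ExpressionMatrix(subject_ids=subjects, probe_ids=list(probes),
                               levels=levels, groups=groups)
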