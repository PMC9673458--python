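"""The 13-node health case study of rural older adults in China.

Thirteen concepts: self-rated health (the outcome, ``R``) and twelve factors
in four first-level groups — lifestyle (C1–C5), health management (C6–C7),
socio-economic status (C8–C10) and living environment (C11–C12).  Initial
states are PLTSs on the tau=5 state scale over the three terms
``{s-3, s0, s3}`` (poor / average / good), summarizing survey proportions
from national ageing databases (CLHLS / CHARLS / CGSS waves).

The connection matrix is elicited from experts and is *not* bundled: a blank
matrix template with the right row/column ids is shipped instead, to be
transcribed from an external source and attached with :func:`attach_matrix`.
Without a matrix the fixture still supports defuzzification and algebra.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .model import ModelError, PLFCModel, load_model, read_matrix

#: Underlying survey proportions behind each node's PLTS (metadata only;
#: the mapping of multi-category percentages onto the three-term states is
#: taken as given, not re-derived here).
SURVEY_NOTES: dict[str, str] = {
    "R": "very good 8.78%, good 35.35%, so-so 40.38%, bad 13.8%, very bad 1.8%",
    "C1": "fresh fruit/vegetable intake: daily 12.76%/55.22%, often 26.06%/32.64%",
    "C2": "sleep quality: very good 15.94%, good 45.58%, so-so 26.65%, bad 10.48%",
    "C3": "physical exercise: yes 25.45%, no 74.55%",
    "C4": "smoking 30.48% / drinking 25.56% prevalence",
    "C5": "low mood >= 2 weeks in last 12 months: yes 12.48%",
    "C6": "annual physical examination: yes 57.7%",
    "C7": "cooperates with doctors on chronic disease: yes 66.76%",
    "C8": "family economic level: below average 39.29%, average 55.36%",
    "C9": "main occupation before 60: agriculture and related 75.02%",
    "C10": "education: illiterate 58.15%, primary 30.9%, junior middle 6.48%",
    "C11": "air/water/industrial-waste pollution severity, mixed",
    "C12": "sees children daily 20.78% ... once a year 19.44%",
}


def _fixture_path(name: str) -> Path:
    return Path(resources.files("plfcm").joinpath("data", name))  # type: ignore[arg-type]


def load_case_study() -> PLFCModel:
    """Load the packaged 13-node fixture (states only, no edges)."""
    return load_model(_fixture_path("case_study.yaml"))


def case_study_path() -> Path:
    """Filesystem path of the packaged fixture (for CLI echoes and docs)."""
    return _fixture_path("case_study.yaml")


def matrix_template_path() -> Path:
    """Filesystem path of the blank connection-matrix template."""
    return _fixture_path("matrix_template.csv")


def attach_matrix(model: PLFCModel, matrix_path: str | Path) -> PLFCModel:
    """Attach a transcribed connection matrix to a states-only model."""
    edges = read_matrix(matrix_path, model.weight_scale)
    known = set(model.node_ids)
    for src, dst in edges:
        if src not in known or dst not in known:
            raise ModelError(
                f"{matrix_path}: matrix id {src!r}->{dst!r} not among model nodes"
            )
    return model.with_edges(edges)
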