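"""Bundled fixtures: the six-object heart sample and schemas for the three
UCI clinical benchmarks (hepatitis, Wisconsin breast cancer, Statlog heart).

Only schemas are shipped; the UCI tables themselves must be downloaded by the
user and fed to the CLI or :func:`roughnet.core.read_table`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import AttributeSchema, InformationSystem, read_schema, read_table

#: Attribute order used by reduct bitmasks for the hepatitis dataset
#: (the 18 conditions surviving preprocessing; Protime is dropped).
HEPATITIS_SEQUENCE: tuple[str, ...] = (
    "Age", "Sex", "Steroid", "Antivirals", "Fatigue", "Malaise", "Anorexia",
    "Liver big", "Liver firm", "Spleen palpable", "Spiders", "Ascites",
    "Varices", "Bilirubin", "Alk phosphate", "Sgot", "Albumin", "Histology",
)

#: Attribute order used by reduct bitmasks for the breast cancer dataset.
BREAST_SEQUENCE: tuple[str, ...] = (
    "Clump thickness", "Uniformity of cell size", "Uniformity of cell shape",
    "Marginal adhesion", "Single epithelial cell size", "Bare nuclei",
    "Bland chromatin", "Normal nucleoli", "Mitoses",
)

#: Attribute order used by reduct bitmasks for the Statlog heart dataset.
HEART_SEQUENCE: tuple[str, ...] = (
    "age", "sex", "Chp", "Bp", "Sch", "Fbs", "Ecg", "Mhrt", "Exian", "Opk",
    "slope", "vessel", "Thal",
)


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(resources.files("roughnet").joinpath("data", name)))


def heart_sample_schema() -> list[AttributeSchema]:
    return read_schema(data_path("heart_sample_schema.yaml"))


def load_heart_sample() -> InformationSystem:
    """The six-object, three-attribute heart-disease sample table."""
    return read_table(data_path("heart_sample.csv"), heart_sample_schema())


def hepatitis_schema() -> list[AttributeSchema]:
    return read_schema(data_path("hepatitis_schema.yaml"))


def breast_schema() -> list[AttributeSchema]:
    return read_schema(data_path("breast_schema.yaml"))


def heart_schema() -> list[AttributeSchema]:
    return read_schema(data_path("heart_schema.yaml"))
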