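"""Cine DENSE cardiac MRI analysis with an analytic deformation phantom.

Displacement encoding with stimulated echoes (DENSE) stores the in-plane
tissue displacement accrued since end-diastole in the image phase
(u = phi / (2 pi ke)).  This package implements the full analysis chain —
phase unwrapping, motion-guided segmentation, tissue tracking, layer and
16-segment strains, twist/torsion, CURE/RURE synchrony indices, and LV
volumetrics — together with a closed-form left-ventricular deformation
phantom whose ground truth makes every stage verifiable.
"""

from importlib import resources

from .model import (
    AcquisitionMeta,
    ContourSet,
    DenseSlice,
    DenseStudy,
    validate_encoding_range,
)
from .io import read_study, write_study
from .phantom import GroundTruth, Phantom, PhantomConfig, plan_slices
from .pipeline import AnalysisSettings, analyze_study

__version__ = "0.1.0"


def builtin_config_path(name: str):
    """Path to a packaged phantom configuration (``lowfat`` or ``highfat``)."""
    return resources.files("cinedense.configs") / f"{name}.yaml"


def load_builtin_config(name: str) -> PhantomConfig:
    return PhantomConfig.from_yaml(str(builtin_config_path(name)))
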