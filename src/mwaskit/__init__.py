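"""mwaskit: untargeted LC-HRMS metabolome-wide association pipeline.

Stages: synthetic data generation, feature QC/preprocessing, biomarker
exposure classification, covariate residualization, PLS-DA/VIP feature
selection, logistic association with FDR control, accurate-mass
annotation and pathway enrichment with a gamma-modeled resampling null.
"""

from importlib import resources

from .core_io import (  # noqa: F401
    FeatureTable,
    Mode,
    MzFeature,
    PathwayDB,
    ReferenceLibrary,
    SampleRecord,
    monoisotopic_mass,
    read_feature_table,
    read_samples,
    write_feature_table,
    write_samples,
)

__version__ = "0.1.0"


def load_bundled_library() -> ReferenceLibrary:
    """The packaged authentic-standard mini-library (biomarkers plus the
    confirmed discriminative metabolites, with platform m/z and RT).

    Note: the retinol entry is recorded as [M+H-H2O]+ because its library
    m/z corresponds to the dehydrated protonated ion.
    """
    path = resources.files("mwaskit").joinpath("data/reference_library.json")
    with resources.as_file(path) as p:
        return ReferenceLibrary.from_json(p)
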