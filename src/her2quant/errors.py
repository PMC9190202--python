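"""Exception hierarchy shared by all her2quant modules.

Categories map onto CLI exit behaviour: configuration/data problems exit 1
with the category name; usage problems are handled by click and exit 2.
"""


class Her2QuantError(Exception):
    """Base class for all package errors."""

    category = "error"


class ConfigurationError(Her2QuantError):
    """Invalid model / run configuration."""

    category = "config"


class DataError(Her2QuantError):
    """Invalid or inconsistent input data (labels, image sizes, manifests)."""

    category = "data"


class ShapeError(Her2QuantError):
    """Array shape mismatch between inputs and parameters."""

    category = "shape"


class NumericalError(Her2QuantError):
    """Numerically invalid quantity (e.g. non-positive BN standard deviation)."""

    category = "numeric"


class InvalidStateError(Her2QuantError):
    """Operation applied to a model in the wrong mode/state."""

    category = "state"


class NoTumorTilesError(Her2QuantError):
    """Slide contains no tiles predicted as a scored (0/1+/2+/3+) class."""

    category = "no-tumor"
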