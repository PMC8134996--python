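"""Exception types shared across the package."""


class WoundMetricsError(Exception):
    """Base class for all package-specific errors."""


class RoiFormatError(WoundMetricsError):
    """Byte stream is not a valid ImageJ ROI record."""


class UnsupportedRoiTypeError(RoiFormatError):
    """ROI record is valid but of a type outside the supported subset."""

    def __init__(self, type_code: int, type_name: str = "unknown"):
        self.type_code = type_code
        self.type_name = type_name
        super().__init__(
            f"unsupported ROI type code {type_code} ({type_name}); "
            "supported types are polygon (0), freehand (7) and traced (8)"
        )


class ValidationError(WoundMetricsError, ValueError):
    """Input violates a documented precondition."""


class UndefinedReferenceError(WoundMetricsError):
    """Reference area is zero, so reference-normalized error measures are undefined."""


class DegenerateSampleError(WoundMetricsError):
    """Sample carries no information for the requested statistical test."""
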