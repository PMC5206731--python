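"""Exception types raised across the package.

All inherit from :class:`ValueError` so that callers who do not care about
the fine-grained category can catch a single base class.
"""


class FiberAlignError(ValueError):
    """Base class for all fiberalign errors."""


class DomainError(FiberAlignError):
    """An angle or parameter lies outside its documented domain."""


class EmptyInputError(FiberAlignError):
    """An operation that requires at least one observation received none."""


class EmptyStatisticsError(FiberAlignError):
    """A summary statistic was requested on a field with no valid cells."""


class DegenerateSegmentError(FiberAlignError):
    """A segment with coincident endpoints has no orientation."""


class ConfigError(FiberAlignError):
    """An analysis or simulation configuration is infeasible or invalid."""


class FiberTableError(FiberAlignError):
    """A fiber/boundary/field table failed to parse; message names the record."""
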