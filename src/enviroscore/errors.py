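"""Exception hierarchy shared across the package."""


class EnviroscoreError(ValueError):
    """Base class for all domain errors raised by this package."""


class UnknownCategoryError(EnviroscoreError):
    """An impact-category code is not part of the known vocabulary."""

    def __init__(self, codes):
        codes = sorted(set(codes))
        self.codes = codes
        super().__init__(f"unknown impact category code(s): {', '.join(codes)}")


class MissingCategoryError(EnviroscoreError):
    """A required impact category has no value."""

    def __init__(self, codes, context=""):
        codes = sorted(set(codes))
        self.codes = codes
        where = f" in {context}" if context else ""
        super().__init__(f"missing impact category value(s){where}: {', '.join(codes)}")


class CategoryMismatchError(EnviroscoreError):
    """Two tables do not cover the same set of categories."""

    def __init__(self, only_left, only_right):
        self.only_left = sorted(only_left)
        self.only_right = sorted(only_right)
        super().__init__(
            "category sets differ: "
            f"only in first = {self.only_left or '[]'}, only in second = {self.only_right or '[]'}"
        )


class SchemaError(EnviroscoreError):
    """A CSV or config file does not conform to its declared schema."""
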