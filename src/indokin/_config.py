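"""Access to the shipped default-parameter configuration."""

import tomllib
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=1)
def load_defaults() -> dict:
    """Parsed contents of the packaged ``defaults.toml`` (cached)."""
    with resources.files("indokin").joinpath("defaults.toml").open("rb") as fh:
        return tomllib.load(fh)
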