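"""Version lookup shared by manifests and the CLI."""

from importlib.metadata import PackageNotFoundError, version


def package_version() -> str:
    try:
        return version("vinecompact")
    except PackageNotFoundError:  # pragma: no cover
        return "0+unknown"
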