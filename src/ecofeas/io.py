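"""Reading and writing network parameter files.

A network file is a YAML document with keys ``sigma`` (row-major matrix),
``d``, ``N0``, optional ``mu`` and free-form ``metadata``.  The reader
validates the container invariants and reports the first violated one.
Population indices in files and error messages are 1-based.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .network import EnergeticNetwork, NetworkInputError

__all__ = ["read_network", "write_network", "example_two_population_network",
           "example_network_path"]

_REQUIRED = ("sigma", "d", "N0")


def read_network(path) -> EnergeticNetwork:
    """Load a network from a YAML parameter file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise NetworkInputError(f"{path}: network file must be a mapping")
    for key in _REQUIRED:
        if key not in doc:
            raise NetworkInputError(f"{path}: missing required key '{key}'")
    try:
        return EnergeticNetwork(
            sigma=np.asarray(doc["sigma"], float),
            d=np.asarray(doc["d"], float),
            N0=np.asarray(doc["N0"], float),
            mu=None if doc.get("mu") is None else np.asarray(doc["mu"], float),
            metadata=doc.get("metadata") or {},
        )
    except NetworkInputError as err:
        raise NetworkInputError(f"{path}: {err}") from err


def write_network(net: EnergeticNetwork, path) -> None:
    doc = {
        "sigma": [[float(x) for x in row] for row in net.sigma],
        "d": [float(x) for x in net.d],
        "N0": [float(x) for x in net.N0],
        "mu": [float(x) for x in net.mu],
        "metadata": net.metadata,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def example_network_path():
    """Path of the packaged two-population example network."""
    return resources.files("ecofeas").joinpath("data/two_population_example.yaml")


def example_two_population_network() -> EnergeticNetwork:
    """The packaged two-population worked example (d=(1.20, 1.80),
    sigma=((1.45, 1.77), (0.45, 1.98)), N0=(1.00, 1.20))."""
    ref = example_network_path()
    with resources.as_file(ref) as path:
        net = read_network(path)
    return net


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()
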