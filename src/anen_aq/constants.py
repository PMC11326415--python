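"""Shared naming conventions for the forecast cubes.

Variable names follow the CAMS/ECMWF short-name habit: ``pm10``, ``pm2p5``
and ``pm1`` are particulate-matter mass concentrations, ``aod`` is dust
aerosol optical depth at 550 nm, ``t2m`` the 2-metre temperature, ``blh``
the boundary-layer height, and ``u10``/``v10`` the 10-metre wind components.
"""

#: Predictor roster used in the similarity metric; the target comes first.
DEFAULT_VARIABLES: tuple[str, ...] = (
    "pm10",
    "pm2p5",
    "pm1",
    "aod",
    "t2m",
    "blh",
    "u10",
    "v10",
)

#: The variable being post-processed (and the one observations exist for).
TARGET_VARIABLE = "pm10"

#: Units attribute for particulate-matter fields after preparation.
PM_UNITS = "ug m-3"

#: Dimension names of a forecast cube.
INIT_DIM = "init_time"
LEAD_DIM = "lead_time"
VALID_DIM = "valid_time"
LAT_DIM = "lat"
LON_DIM = "lon"
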