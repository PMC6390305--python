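"""Great-circle distances and the published sampling-site coordinates.

Coordinates are decimal degrees (N positive, W negative) for the six
Fundulus heteroclitus sampling sites: two thermal-effluent (TE) sites, each
flanked by a northern and a southern reference, forming two triads.
"""

import math

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

# (latitude, longitude); converted from the published degree-minute-second
# positions of each collection site.
STUDY_SITES = {
    "oyster_creek_te": (39.808722, -74.184367),  # Forked River, NJ
    "mantoloking": (40.050006, -74.068033),      # northern reference, NJ
    "tuckerton": (39.508778, -74.324475),        # southern reference, NJ (RUMFS)
    "brayton_point_te": (41.712497, -71.186039), # Mount Hope Bay marsh, MA
    "horseneck_beach": (41.504489, -71.025564),  # northern reference, MA
    "matunuck": (41.382347, -71.525567),         # southern reference, RI
}


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def site_distance_km(a: str, b: str) -> float:
    """Distance between two named study sites."""
    (la1, lo1), (la2, lo2) = STUDY_SITES[a], STUDY_SITES[b]
    return haversine_km(la1, lo1, la2, lo2)
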