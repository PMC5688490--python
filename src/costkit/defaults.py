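"""Packaged default factor-share proportions.

These are the published estimates from a translog cost-function fit to a
six-country facility-level dataset of voluntary medical male circumcision
(VMMC) services: one equation for hospitals (applied to inpatient-day hotel
costs) and one for health centres (applied to outpatient-visit hotel costs).
They are shipped verbatim as published; the health-centre row sums to 0.969
as printed and is deliberately not renormalized by default.
"""

from .types import FactorShares

DEFAULT_FACTOR_SHARES = {
    "hospital": FactorShares(
        level="hospital",
        s_personnel=0.390,
        s_consumables=0.317,
        s_odc=0.098,
        s_indirect=0.195,
    ),
    "health_centre": FactorShares(
        level="health_centre",
        s_personnel=0.360,
        s_consumables=0.234,
        s_odc=0.085,
        s_indirect=0.290,
    ),
}
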