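"""Derive the climatic water content (CWC) covariate step by step.

PET from temperature and radiation, rainfall events from the PET
threshold, mean dry-spell length, available water capacity from soil
texture, and finally the time-averaged water content of the
exponentially drying store.
"""
import numpy as np

from soilrich import SimulationConfig, simulate_weather
from soilrich.climate import (
    SoilRecord, annual_pet, awc_pedotransfer, climatic_water_content,
    consecutive_dry_days, detect_rain_events,
)

cfg = SimulationConfig(seed=3)
weather = simulate_weather(cfg, site_index=5)

pet = annual_pet(weather)
events = detect_rain_events(weather, pet)
dry = consecutive_dry_days(events, len(weather))
soil = SoilRecord(BLD=1350, ORC=15, SLT=0.35, CLY=0.20, SND=0.45, PH=6.5, CEC=18)
awc = awc_pedotransfer(soil)
cwc = climatic_water_content(awc, dry, pet)

print(f"mean annual PET:      {pet:7.1f} mm/yr (daily threshold {pet/365.25:.2f} mm)")
print(f"rainfall events:      {len(events):7d} in {len(weather)} days")
print(f"mean dry spell (DRY): {dry:7.1f} days")
print(f"water capacity (AWC): {awc:7.3f} (volumetric, top metre)")
print(f"climatic water content: {cwc:.3f}  -- the store refills at each event and")
print("dries exponentially; CWC is its time average over a typical dry spell")
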