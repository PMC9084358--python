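# Sector-name -> budget-category mapping (editable).
# IFF: industrial fossil fuel; AGW: agriculture, landfills and waste;
# WET: natural wetlands; BB: biomass burning; GEO: geological seeps;
# OTH: other natural sources; SOIL: soil microbial uptake (sink magnitude).
coal: IFF
oil: IFF
gas: IFF
oil_gas: IFF
fossil_fuel: IFF
enteric: AGW
enteric_fermentation: AGW
manure: AGW
livestock: AGW
landfill: AGW
landfill_waste: AGW
waste: AGW
wastewater: AGW
rice: AGW
wetlands: WET
wetlands_tropical: WET
wetlands_boreal: WET
biomass_burning: BB
wildfires: BB
agricultural_fires: BB
geological: GEO
seeps: GEO
termites: OTH
freshwater: OTH
wild_animals: OTH
oceans: OTH
other_natural: OTH
soil: SOIL
soil_uptake: SOIL
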