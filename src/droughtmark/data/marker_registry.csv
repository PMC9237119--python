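marker,bp_set,subgroup,units,cf,name
SOD,stress-response,,umol O2 gDW-1 min-1,4,Superoxide dismutase activity
APX,stress-response,,umol Asa gDW-1 min-1,4,Ascorbate peroxidase activity
POX,stress-response,,umol purpurogalline gDW-1 min-1,4,Phenol peroxidase activity
CAT,stress-response,,umol H2O2 gDW-1 min-1,4,Catalase activity
PRO,stress-response,,ug gFW-1,3,Free proline
MDA,stress-response,,umol gFW-1,2,Malondialdehyde
CHL,stress-response,,ug gFW-1,3,Total chlorophyll
CAR,stress-response,,ug gFW-1,2,Total carotenoid
LAI,growth,,dimensionless,1,Leaf area index
LAR,growth,,cm2 g-1,3,Leaf area ratio
NAR,growth,,g cm-2 day-1,3,Net assimilation rate
RGR,growth,,g g-1 day-1,3,Relative growth rate
CGR,growth,,g cm-2 day-1,3,Crop growth rate
RWC,water-use,physiological,percent,3,Relative water content
WUE,water-use,physiological,g kg-1,1,Water use efficiency
CTD,water-use,physiological,degC,2,Canopy temperature depression
LT,water-use,morphological,um,3,Leaf thickness
TD_AB,water-use,morphological,mm-2,2,"Trichome density, abaxial"
TD_AD,water-use,morphological,mm-2,2,"Trichome density, adaxial"
SD_AB,water-use,morphological,mm-2,2,"Stomatal density, abaxial"
SD_AD,water-use,morphological,mm-2,2,"Stomatal density, adaxial"
SA,water-use,morphological,um,3,Stomatal aperture
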