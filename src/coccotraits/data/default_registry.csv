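family,genus,species,morpho_group,life_cycle_phase,shape_class,ks_body,ks_spinose,ks_exothecal,size_metric,y_fraction,y_fraction_incl_process,cn_multiplier,fixed_cn,fixed_cl,fixed_spine_length,dimorphic_spinose_fraction,appendage_pg_per_appendage,appendage_default_count,appendage_fixed_total_pg,coccolith_thickness,umbellosphaera_cl_factor,source_note
Noelaerhabdaceae,Emiliania,huxleyi,,heterococcolith,prolate_sphere,0.02,,0.02,distal_shield_length,0.86,,2,,,,,,,,0.13,,single Ks policy across morphotypes; recommended literature Ks for small placoliths; multilayer thickness 0.13 um
Noelaerhabdaceae,Gephyrocapsa,,,heterococcolith,prolate_sphere,0.05,,0.02,distal_shield_length,0.65,,2,,,,,,,,,,placeholder: Ks and y from cited literature only; confirm before quantitative use
Calcidiscaceae,Calcidiscus,,,heterococcolith,prolate_sphere,0.08,,0.02,distal_shield_length,0.42,,2,,,,,,,,,,placeholder Ks from cited literature; y mean 42% from LM calibration
Calcidiscaceae,Oolithotus,,,heterococcolith,prolate_sphere,0.055,,0.02,distal_shield_length,0.6,,2,,,,,,,,,,placeholder: Ks and y from cited literature only; confirm before quantitative use
Calcidiscaceae,Umbilicosphaera,,,heterococcolith,prolate_sphere,0.06,,0.02,distal_shield_length,0.6,,2,,,,,,,,,,placeholder: Ks and y from cited literature only; confirm before quantitative use
Helicosphaeraceae,Helicosphaera,,,heterococcolith,prolate_sphere,0.05,,0.02,distal_shield_length,0.51,,2,,,,,,,,,,placeholder Ks from cited literature; y mean 51% from LM calibration
Calciosoleniaceae,Calciosolenia,,,heterococcolith,double_cone,0.007,,0.02,distal_shield_length,0.8,,2,,,,,,,,,,Ks back-calculated from 2.5 pg coccolith calcite at 5 um length; y placeholder
Rhabdosphaeraceae,Rhabdosphaera,clavigera,,heterococcolith,prolate_sphere,0.025,0.012,0.02,distal_shield_length,0.6,0.3,2,,,5,0.5,,,,,,body Ks modified from Acanthoica; 50/50 dimorphic split with 5 um spine fallback; spinose Ks placeholder; y placeholder
Rhabdosphaeraceae,Discosphaera,tubifera,,heterococcolith,prolate_sphere,0.02,,0.02,trumpet_width,0.6,0.3,2,,,,,,,,,,placeholder Ks; calcite computed from trumpet width; y placeholder
Rhabdosphaeraceae,Acanthoica,,,heterococcolith,prolate_sphere,0.025,,0.02,distal_shield_length,0.56,,2,,,,,,,,,,y mean 56% of coccosphere volume; polar-spine calcite not modelled; Ks placeholder
Syracosphaeraceae,Syracosphaera,,pulchra group,heterococcolith,prolate_sphere,0.03,,0.02,distal_shield_length,0.65,,2,,,,,,,,,,robust inner-wall-cycle morpho-group; y 65%
Syracosphaeraceae,Syracosphaera,,molischii group,heterococcolith,prolate_sphere,0.022,,0.02,distal_shield_length,0.75,,2,,,,,,,,,,intermediate Ks for well-developed rims without central boss; y 75%
Syracosphaeraceae,Syracosphaera,,nodosa group,heterococcolith,prolate_sphere,0.015,,0.02,distal_shield_length,0.75,,2,,,,,,,,,,small-species Ks for forms without inner wall cycle or central structure; y 75%
Syracosphaeraceae,Syracosphaera,,,heterococcolith,prolate_sphere,0.02,,0.02,distal_shield_length,0.75,,2,,,,,,,,,,genus-level fallback for coccospheres not identified to species; y adopted from the common morpho-group value
Syracosphaeraceae,Michaelsarsia,,,heterococcolith,prolate_sphere,0.02,,0.02,distal_shield_length,0.75,,2,,,,,12.5,8,,,,body Ks adapted from Syracosphaera (placeholder); 12.5 pg per appendage from 4 segments at Ks 0.007 and 5.5 um; 8 appendages assumed when uncounted
Syracosphaeraceae,Ophiaster,,,heterococcolith,prolate_sphere,0.015,,0.02,distal_shield_length,0.75,,2,,,,,,,33,,,body Ks adapted from Syracosphaera (placeholder); fixed 33 pg appendage calcite when arms present
Alisphaeraceae,Alisphaera,,,heterococcolith,prolate_sphere,0.02,,0.02,distal_shield_length,0.75,,2,,,,,,,,,,placeholder Ks and y; confirm before quantitative use
Alisphaeraceae,Alisphaera,,,polycrater,prolate_sphere,0.02,,0.02,distal_shield_length,0.75,,2,400,0.8,,,,,,,,polycrater phase: fixed C_N 400 and C_L 0.8 um when counting/measuring impossible; Ks and y placeholder
Umbellosphaeraceae,Umbellosphaera,,,heterococcolith,prolate_sphere,0.03,,0.02,distal_shield_length,0.5,,3,,,,,,,,,0.7,placeholder Ks from cited literature; visible coccoliths x3 for pseudo-multilayer; average C_L = 0.7 x C_L max; y placeholder
,Florisphaera,profunda,,nannolith,prolate_sphere,0.03,,0.02,distal_shield_length,0.1,,2,145,,,,,,,,,nannolith Ks 0.03; fixed C_N 145; cell volume 10% of coccosphere volume
,*,,,holococcolith,prolate_sphere,0.036,,0.02,distal_shield_length,0.8,,2,,,,,,,,,,holococcolith default: estimated Ks 0.036 and y 80% for all holococcolith-bearing coccospheres
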