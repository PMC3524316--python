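@prefix prov: <http://www.w3.org/ns/prov#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix skos: <http://www.w3.org/2004/02/skos/core#> .
@prefix syspro: <http://example.org/syspro#> .

syspro:Bait_Type a rdfs:Class ;
    rdfs:label "Bait Type" ;
    rdfs:subClassOf prov:Entity .

syspro:Bait_gene a rdfs:Class ;
    rdfs:label "Bait gene" ;
    rdfs:subClassOf prov:Entity ;
    skos:altLabel "Bait Gene Symbol" .

syspro:Cell_line a rdfs:Class ;
    rdfs:label "Cell line" ;
    rdfs:subClassOf syspro:Sample .

syspro:Experiment_Type a rdfs:Class ;
    rdfs:label "Experiment Type" ;
    rdfs:subClassOf prov:Activity .

syspro:Organism a rdfs:Class ;
    rdfs:label "Organism" ;
    rdfs:subClassOf syspro:Sample .

syspro:Perturbation a rdfs:Class ;
    rdfs:label "Perturbation" ;
    rdfs:subClassOf prov:Activity .

syspro:Researcher a rdfs:Class ;
    rdfs:label "Researcher" ;
    rdfs:subClassOf prov:Agent .

syspro:Run_Group a rdfs:Class ;
    rdfs:label "Run Group" ;
    rdfs:subClassOf prov:Activity .

syspro:Sample a rdfs:Class ;
    rdfs:label "Sample" ;
    rdfs:subClassOf prov:Entity .

syspro:Sample_Type a rdfs:Class ;
    rdfs:label "Sample Type" ;
    rdfs:subClassOf syspro:Sample .

syspro:Subcellular_Fraction a rdfs:Class ;
    rdfs:label "Subcellular Fraction" ;
    rdfs:subClassOf syspro:Sample .

prov:Activity a rdfs:Class ;
    rdfs:label "Activity" .

prov:Agent a rdfs:Class ;
    rdfs:label "Agent" .

prov:Entity a rdfs:Class ;
    rdfs:label "Entity" .

syspro:i_Bait_Type__Endogenous a syspro:Bait_Type ;
    rdfs:label "Endogenous" .

syspro:i_Bait_Type__Exogenous a syspro:Bait_Type ;
    rdfs:label "Exogenous" .

syspro:i_Bait_Type__KnockIn a syspro:Bait_Type ;
    rdfs:label "KnockIn" .

syspro:i_Bait_Type__Tagged a syspro:Bait_Type ;
    rdfs:label "Tagged" .

syspro:i_Bait_Type__Untagged a syspro:Bait_Type ;
    rdfs:label "Untagged" .

syspro:i_Bait_gene__APC a syspro:Bait_gene ;
    rdfs:label "APC" .

syspro:i_Bait_gene__CTNNB1 a syspro:Bait_gene ;
    rdfs:label "CTNNB1" ;
    prov:hadRole syspro:i_Cell_line__RKO .

syspro:i_Bait_gene__DNMT1 a syspro:Bait_gene ;
    rdfs:label "DNMT1" .

syspro:i_Bait_gene__EPHB2 a syspro:Bait_gene ;
    rdfs:label "EPHB2" ;
    prov:hadRole syspro:i_Cell_line__HCT116 .

syspro:i_Bait_gene__POU5F1 a syspro:Bait_gene ;
    rdfs:label "POU5F1" .

syspro:i_Cell_line__Embryonic_stem a syspro:Cell_line ;
    rdfs:label "Embryonic stem" .

syspro:i_Cell_line__Epilast_stem_cell a syspro:Cell_line ;
    rdfs:label "Epilast stem cell" .

syspro:i_Cell_line__T_cells_Boom a syspro:Cell_line ;
    rdfs:label "T-cells (Boom)" .

syspro:i_Experiment_Type__AP_MS a syspro:Experiment_Type ;
    rdfs:label "AP-MS" .

syspro:i_Experiment_Type__Protein_Expression a syspro:Experiment_Type ;
    rdfs:label "Protein Expression" .

syspro:i_Organism__Drosophila_melanogaster a syspro:Organism ;
    rdfs:label "Drosophila melanogaster" .

syspro:i_Organism__Homo_Sapiens a syspro:Organism ;
    rdfs:label "Homo Sapiens" .

syspro:i_Organism__Mus_musculus a syspro:Organism ;
    rdfs:label "Mus musculus" .

syspro:i_Perturbation__10_ng a syspro:Perturbation ;
    rdfs:label "10 ng" .

syspro:i_Perturbation__Dose_0 a syspro:Perturbation ;
    rdfs:label "Dose = 0" .

syspro:i_Perturbation__Not_Applicable a syspro:Perturbation ;
    rdfs:label "Not Applicable" .

syspro:i_Perturbation__WNT3A a syspro:Perturbation ;
    rdfs:label "WNT3A" .

syspro:i_Run_Group__Bait a syspro:Run_Group ;
    rdfs:label "Bait" .

syspro:i_Run_Group__No_Vector_Control a syspro:Run_Group ;
    rdfs:label "No Vector Control" .

syspro:i_Run_Group__Treated a syspro:Run_Group ;
    rdfs:label "Treated" .

syspro:i_Sample_Type__Cell_culture a syspro:Sample_Type ;
    rdfs:label "Cell culture" .

syspro:i_Subcellular_Fraction__Cytosol a syspro:Subcellular_Fraction ;
    rdfs:label "Cytosol" .

syspro:i_Cell_line__HCT116 a syspro:Cell_line ;
    rdfs:label "HCT116" .

syspro:i_Cell_line__RKO a syspro:Cell_line ;
    rdfs:label "RKO" .

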