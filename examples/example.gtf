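chr1	sim	gene	98985	98985	.	.	.	gene_id "feat0";
chr1	sim	gene	343883	343883	.	.	.	gene_id "feat1";
chr1	sim	gene	431899	431899	.	.	.	gene_id "feat2";
chr1	sim	gene	435530	435530	.	.	.	gene_id "feat3";
chr1	sim	gene	576923	576923	.	.	.	gene_id "feat4";
chr1	sim	gene	707855	707855	.	.	.	gene_id "feat5";
chr1	sim	gene	1027845	1027845	.	.	.	gene_id "feat6";
chr1	sim	gene	1209020	1209020	.	.	.	gene_id "feat7";
chr1	sim	gene	2000251	2000251	.	.	.	gene_id "feat8";
chr1	sim	gene	2072634	2072634	.	.	.	gene_id "feat9";
chr1	sim	gene	2092985	2092985	.	.	.	gene_id "feat10";
chr1	sim	gene	2247420	2247420	.	.	.	gene_id "feat11";
chr1	sim	gene	2250680	2250680	.	.	.	gene_id "feat12";
chr1	sim	gene	2428866	2428866	.	.	.	gene_id "feat13";
chr1	sim	gene	3540024	3540024	.	.	.	gene_id "feat14";
chr1	sim	gene	3712428	3712428	.	.	.	gene_id "feat15";
chr1	sim	gene	3766323	3766323	.	.	.	gene_id "feat16";
chr1	sim	gene	3981913	3981913	.	.	.	gene_id "feat17";
chr2	sim	gene	199928	199928	.	.	.	gene_id "feat18";
chr2	sim	gene	237148	237148	.	.	.	gene_id "feat19";
chr2	sim	gene	250938	250938	.	.	.	gene_id "feat20";
chr2	sim	gene	314060	314060	.	.	.	gene_id "feat21";
chr2	sim	gene	395911	395911	.	.	.	gene_id "feat22";
chr2	sim	gene	493032	493032	.	.	.	gene_id "feat23";
chr2	sim	gene	1012676	1012676	.	.	.	gene_id "feat24";
chr2	sim	gene	1198118	1198118	.	.	.	gene_id "feat25";
chr2	sim	gene	1266293	1266293	.	.	.	gene_id "feat26";
chr2	sim	gene	1526994	1526994	.	.	.	gene_id "feat27";
chr2	sim	gene	1533828	1533828	.	.	.	gene_id "feat28";
chr2	sim	gene	1644226	1644226	.	.	.	gene_id "feat29";
chr2	sim	gene	1835054	1835054	.	.	.	gene_id "feat30";
chr2	sim	gene	1965736	1965736	.	.	.	gene_id "feat31";
chr2	sim	gene	2272304	2272304	.	.	.	gene_id "feat32";
chr2	sim	gene	2394273	2394273	.	.	.	gene_id "feat33";
chr2	sim	gene	2510110	2510110	.	.	.	gene_id "feat34";
chr2	sim	gene	2603820	2603820	.	.	.	gene_id "feat35";
chr2	sim	gene	2628315	2628315	.	.	.	gene_id "feat36";
chr2	sim	gene	2724674	2724674	.	.	.	gene_id "feat37";
chr2	sim	gene	2844060	2844060	.	.	.	gene_id "feat38";
chr2	sim	gene	2897118	2897118	.	.	.	gene_id "feat39";
chr2	sim	gene	3136515	3136515	.	.	.	gene_id "feat40";
chr2	sim	gene	3151238	3151238	.	.	.	gene_id "feat41";
chr2	sim	gene	3198374	3198374	.	.	.	gene_id "feat42";
chr2	sim	gene	3449669	3449669	.	.	.	gene_id "feat43";
chr2	sim	gene	3637966	3637966	.	.	.	gene_id "feat44";
chr2	sim	gene	3861187	3861187	.	.	.	gene_id "feat45";
chr2	sim	gene	3972283	3972283	.	.	.	gene_id "feat46";
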