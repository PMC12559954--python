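# Newly proposed taxa: one row per described species or combination.
# Rank-status columns: "new" = newly proposed name, "described" = previously
# described taxon the row is placed in. species_status: "new" | "combination".
# Family names are the one-per-new-order "...aceae fam. nov." names from the
# formal taxon descriptions. Data entry from the printed source, not computation.
phylum	phylum_status	class	class_status	order	order_status	family	family_status	genus	genus_status	species	species_status	aliases
Aldinomycota	new	Aldinomycetes	new	Aldinomycetales	new	Aldinomycetaceae	new	Aldinomyces	new	Aldinomyces tarquinii	new
Aphelidiomycota	described	Pantelleriomycetes	new	Pantelleriales	new	Pantelleriaceae	new	Pantelleria	new	Pantelleria saittana	new
Borikeniomycota	new	Borikeniomycetes	new	Borikeniales	new	Borikeniaceae	new	Borikenia	new	Borikenia urbinana	new	Borikenia urbinae
Calcarisporiellomycota	described	Calcarisporiellomycetes	described	Terrincolales	new	Terrincolaceae	new	Terrincola	new	Terrincola waldropii	new
Chytridiomycota	described	Aquaeurochytriomycetes	new	Aquaeurochytriales	new	Aquieurochytriaceae	new	Aquieurochytrium	new	Aquieurochytrium lacustre	new
Chytridiomycota	described	Edaphochytriomycetes	new	Edaphochytriales	new	Edaphochytriaceae	new	Edaphochytrium	new	Edaphochytrium valuojaense	new
Chytridiomycota	described	Spizellomycetes	described	Paraspizellomycetales	new	Paraspizellomycetaceae	new	Paraspizellomyces	new	Paraspizellomyces parrentiae	new
Chytridiomycota	described	Tibetochytriomycetes	new	Tibetochytriales	new	Tibetochytriaceae	new	Tibetochytrium	new	Tibetochytrium taylorii	new
Chytridiomycota	described	Tropicochytriomycetes	new	Tropicochytriales	new	Tropicochytriaceae	new	Tropicochytrium	new	Tropicochytrium toronegroense	new
Curlevskiomycota	new	Curlevskiomycetes	new	Curlevskiales	new	Curlevskiaceae	new	Curlevskia	new	Curlevskia holarctica	new
Kickxellomycota	described	Parakickxellomycetes	new	Parakickxellales	new	Parakickxellaceae	new	Parakickxella	new	Parakickxella borikenica	new
Mirabilomycota	new	Mirabilomycetes	new	Mirabilomycetales	new	Mirabilomycetaceae	new	Mirabilomyces	new	Mirabilomyces abrukanus	new
Monoblepharomycota	described	Algovoracomycetes	new	Algovoracales	new	Algovoracaceae	new	Algovorax	new	Algovorax scenedesmi	combination	Phlyctidium scenedesmi
Monoblepharomycota	described	Algovoracomycetes	new	Solivoracales	new	Solivoracaceae	new	Solivorax	new	Solivorax pantropicus	new
Mortierellomycota	described	Maerjamycetes	new	Maerjamycetales	new	Maerjamycetaceae	new	Maerjamyces	new	Maerjamyces jumpponenii	new
Mortierellomycota	described	Mortierellomycetes	described	Mycosocceriales	new	Mycosocceriaceae	new	Mycosocceria	new	Mycosocceria estonica	new
Mortierellomycota	described	Ruderaliomycetes	new	Ruderaliales	new	Ruderaliaceae	new	Ruderalia	new	Ruderalia cosmopolita	new
Nematovomycota	new	Nematovomycetes	new	Nematovomycetales	new	Nematovomycetaceae	new	Nematovomyces	new	Nematovomyces soinasteënsis	new
Nematovomycota	new	Nematovomycetes	new	Nematovomycetales	new	Nematovomycetaceae	new	Nematovomyces	new	Nematovomyces vermicola	combination	Olpidium vermicola
Neocallimastigomycota	described	Aquamastigomycetes	new	Aquamastigales	new	Aquamastigaceae	new	Aquamastix	new	Aquamastix sanduskyensis	new
Neocallimastigomycota	described	Cantoromastigomycetes	new	Cantoromastigales	new	Cantoromastigaceae	new	Cantoromastix	new	Cantoromastix holarctica	new
Neocallimastigomycota	described	Dobrisimastigomycetes	new	Dobrisimastigales	new	Dobrisimastigaceae	new	Dobrisimastix	new	Dobrisimastix vlkii	new
Neocallimastigomycota	described	Palomastigomycetes	new	Palomastigales	new	Palomastigaceae	new	Palomastix	new	Palomastix lacustris	new
Neocallimastigomycota	described	Sedimentomastigomycetes	new	Sedimentomastigales	new	Sedimentomastigaceae	new	Sedimentomastix	new	Sedimentomastix tueriensis	new
Olpidiomycota	described	Bryolpidiomycetes	new	Bryolpidiales	new	Bryolpidiaceae	new	Bryolpidium	new	Bryolpidium mundanum	new
Olpidiomycota	described	Chthonolpidiomycetes	new	Chthonolpidiales	new	Chthonolpidiaceae	new	Chthonolpidium	new	Chthonolpidium enigmatum	new
Olpidiomycota	described	Savannolpidiomycetes	new	Savannolpidiales	new	Savannolpidiaceae	new	Savannolpidium	new	Savannolpidium raadiense	new
Rozellomycota	described	Gelotisporidiomycetes	new	Gelotisporidiales	new	Gelotisporidiaceae	new	Gelotisporidium	new	Gelotisporidium boreale	new
Rozellomycota	described	Sumavosporidiomycetes	new	Sumavosporidiales	new	Sumavosporidiaceae	new	Sumavosporidium	new	Sumavosporidium sylvestre	new
Tartumycota	new	Tartumycetes	new	Tartumycetales	new	Tartumycetaceae	new	Tartumyces	new	Tartumyces setoi	new
Waitukubulimycota	new	Waitukubulimycetes	new	Waitukubulimycetales	new	Waitukubulimycetaceae	new	Waitukubulimyces	new	Waitukubulimyces cliftonii	new
Viljandiomycota	new	Viljandiomycetes	new	Viljandiales	new	Viljandiaceae	new	Viljandia	new	Viljandia globalis	new
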