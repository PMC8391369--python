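<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="visited_places" description="lugares visitados que fueron relevantes en su vida">
    <category role="trigger">
      <pattern>VIAJE</pattern>
      <template><random>
        <li>¡Viajar es maravilloso! ¿Es cierto que conociste <get name="lugar_visitado"/>?</li>
        <li>¿Qué lugar de los que visitaste te gustó más?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ VIAJE</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>VIAJE _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ VIAJE _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>VIAJES</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ VIAJES</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>VIAJES _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ VIAJES _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>VIAJAR</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ VIAJAR</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>VIAJAR _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ VIAJAR _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>LUGARES</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ LUGARES</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>LUGARES _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ LUGARES _</pattern>
      <template><srai>VIAJE</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué maravilla! ¿Qué fue lo que más te gustó de <get name="lugar_visitado"/>?</li>
        <li>¿Con quién viajaste a <get name="lugar_visitado"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Entiendo. ¿Qué lugar te gustaría recordar hoy?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Los viajes dejan recuerdos hermosos. ¿Me platicas de un viaje?</li>
        <li>Cada lugar tiene su encanto. ¿Cuál recuerdas con cariño?</li>
      </random></template>
    </category>
  </topic>
</aiml>
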